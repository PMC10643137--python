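"""Run configuration, seed fan-out and run manifests.

A single master seed is fanned out to per-stage seeds through a stable
hash of (master seed, stage name), so stages are reproducible independently
of each other.  Manifests record the configuration hash, seed, input file
checksums and package version so a run can be re-executed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .features import WindowConfig


@dataclass
class RunConfig:
    """Flat, serializable bundle of every tunable constant."""

    seed: int = 0
    # sliding window
    window_len: int = 11
    msd_max_lag: int = 5
    min_traj_len: int = 11
    loc_sd: float = 0.0
    # mixtures
    n_components: int = 2
    n_init: int = 10
    reg_covar: float = 1e-6
    # kinetics
    min_dwells: int = 20
    min_duration_s: float = 5.0
    # ABC
    bin_size: int = 5_000
    search_radius: int = 5_000_000
    strong_quantile: float = 0.90
    merge_gap: int = 500
    min_peak_len: int = 500
    promoter_flank: int = 1_000
    coverage_quantile: float = 0.05

    def window_config(self) -> WindowConfig:
        return WindowConfig(
            window_len=self.window_len,
            msd_max_lag=self.msd_max_lag,
            min_traj_len=self.min_traj_len,
            loc_sd=self.loc_sd,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path, config: RunConfig, inputs: list[str | Path],
    outputs: list[str | Path],
) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
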