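"""Synthetic toy genome for exercising the ABC link-calling pipeline.

Generates, for a single small chromosome: a TSS table, H3K4me3 peaks over
most promoters, condition-specific H3K27ac peak sets with per-base signal,
and a 5 kb binned contact matrix with power-law distance decay
(``C ~ d**-gamma``) plus optional Poisson counting noise and planted
high-contact promoter-element pairs.  Everything is deterministic given a
seed, and small enough to run in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abclinks import DEFAULT_BIN_SIZE, ContactMatrix


@dataclass
class ToyGenome:
    chrom: str
    size: int
    tss: pd.DataFrame
    h3k4me3: pd.DataFrame
    h3k27ac: dict[str, pd.DataFrame]  # per condition
    signal: dict[str, pd.DataFrame]  # bedGraph-style per condition
    contacts: dict[str, ContactMatrix]
    planted: list[tuple[int, int]] = field(default_factory=list)


def power_law_contacts(
    chrom: str,
    size: int,
    gamma: float = 1.0,
    amplitude: float = 100.0,
    bin_size: int = DEFAULT_BIN_SIZE,
    poisson_noise: bool = False,
    planted_pairs: list[tuple[int, int]] | None = None,
    planted_boost: float = 5.0,
    rng: np.random.Generator | None = None,
) -> ContactMatrix:
    """Dense-in-upper-triangle contact matrix with C(d) = amplitude * d**-gamma.

    ``planted_pairs`` are (bin_i, bin_j) pairs whose contact is multiplied
    by ``planted_boost``.  With ``poisson_noise`` the values are Poisson
    draws around the power-law expectation.
    """
    rng = rng or np.random.default_rng(0)
    n = -(-size // bin_size)
    ii, jj = np.triu_indices(n, k=1)
    d = (jj - ii) * bin_size
    vals = amplitude * d.astype(float) ** (-gamma)
    if planted_pairs:
        for a, b in planted_pairs:
            lo, hi = min(a, b), max(a, b)
            m = (ii == lo) & (jj == hi)
            vals = np.where(m, vals * planted_boost, vals)
    if poisson_noise:
        vals = rng.poisson(vals).astype(float)
    t = pd.DataFrame({"chrom": chrom, "bin_i": ii, "bin_j": jj, "value": vals})
    return ContactMatrix(bin_size=bin_size, chrom_sizes={chrom: size}, triplets=t)


def random_peaks(
    rng: np.random.Generator,
    chrom: str,
    size: int,
    n_peaks: int,
    min_len: int = 200,
    max_len: int = 2_000,
) -> pd.DataFrame:
    starts = np.sort(rng.integers(0, size - max_len, size=n_peaks))
    lengths = rng.integers(min_len, max_len, size=n_peaks)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.minimum(starts + lengths, size)}
    )


def make_toy_genome(
    seed: int = 0,
    chrom: str = "chrS",
    size: int = 2_000_000,
    n_genes: int = 20,
    n_enhancers: int = 40,
    gamma: float = 1.0,
    conditions: tuple[str, ...] = ("WT", "KO"),
    poisson_noise: bool = False,
    n_planted: int = 0,
) -> ToyGenome:
    """Build a deterministic toy genome with condition-specific peak sets.

    Roughly 80% of enhancer peaks are shared between conditions and the
    rest are condition-unique; activities differ by condition so link
    rankings diverge.
    """
    rng = np.random.default_rng(seed)
    tss_pos = np.sort(rng.choice(np.arange(10_000, size - 10_000, 5_000),
                                 size=n_genes, replace=False))
    tss = pd.DataFrame(
        {"chrom": chrom, "pos": tss_pos,
         "gene": [f"g{i}" for i in range(n_genes)],
         "strand": rng.choice(["+", "-"], size=n_genes)}
    )
    # H3K4me3 over ~90% of TSS
    has_peak = rng.random(n_genes) < 0.9
    h3k4me3 = pd.DataFrame(
        {"chrom": chrom,
         "start": tss_pos[has_peak] - rng.integers(100, 800, size=int(has_peak.sum())),
         "end": tss_pos[has_peak] + rng.integers(100, 800, size=int(has_peak.sum()))}
    )

    base = random_peaks(rng, chrom, size, n_enhancers, min_len=600, max_len=2_500)
    h3k27ac, signal, contacts = {}, {}, {}
    planted: list[tuple[int, int]] = []
    for cond in conditions:
        keep = rng.random(n_enhancers) < 0.8
        extra = random_peaks(rng, chrom, size, max(2, n_enhancers // 5),
                             min_len=600, max_len=2_500)
        peaks = (
            pd.concat([base[keep], extra], ignore_index=True)
            .sort_values("start")
            .reset_index(drop=True)
        )
        h3k27ac[cond] = peaks
        # piecewise-constant signal: enriched over peaks, low background
        seg = []
        for _, p in peaks.iterrows():
            seg.append((chrom, int(p["start"]), int(p["end"]),
                        float(rng.uniform(2.0, 10.0))))
        signal[cond] = pd.DataFrame(seg, columns=["chrom", "start", "end", "value"])
        pp: list[tuple[int, int]] = []
        if n_planted:
            bins = size // DEFAULT_BIN_SIZE
            for _ in range(n_planted):
                a = int(rng.integers(0, bins - 40))
                pp.append((a, a + int(rng.integers(4, 40))))
            planted.extend(pp)
        contacts[cond] = power_law_contacts(
            chrom, size, gamma=gamma, poisson_noise=poisson_noise,
            planted_pairs=pp or None, rng=rng,
        )
    return ToyGenome(
        chrom=chrom, size=size, tss=tss, h3k4me3=h3k4me3, h3k27ac=h3k27ac,
        signal=signal, contacts=contacts, planted=planted,
    )
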