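"""Activity-by-contact (ABC) enhancer-promoter link calling.

The ABC score of a promoter p and regulatory element r is

    ABC(p, r) = A_r * C(p, r) / sum over s in N(p) of A_s * C(p, s)

where N(p) is the set of candidate regulatory elements within 5 Mb of p,
C is the (5 kb binned) Hi-C contact frequency and A_r is the element's
activity, scored here as the mean per-base H3K27ac signal over the element
(an H3K27ac-only variant of the original DHS x H3K27ac geometric mean).

Regulatory elements are defined per condition from peak tracks:
promoters are +/- 1 kb of a TSS overlapping an H3K4me3 peak; H3K27ac peaks
closer than 500 bp are merged, merged peaks shorter than 500 bp are
discarded, peaks overlapping promoters are discarded, and the union of the
surviving intergenic peaks and the promoters forms the master element list.
Bin pairs with poor Hi-C coverage are imputed from the fitted power-law
distance decay C ~ d**(-gamma).

Strong links are the top decile of the pooled (both conditions) score
distribution; link identity (promoter, element, promoter position) is
matched across conditions to classify links as condition-unique or common.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, InsufficientDataError

log = logging.getLogger(__name__)

PROMOTER = "promoter"
INTERGENIC = "intergenic_re"

DEFAULT_BIN_SIZE = 5_000
SEARCH_RADIUS = 5_000_000
MERGE_GAP = 500
MIN_PEAK_LEN = 500
PROMOTER_FLANK = 1_000
STRONG_QUANTILE = 0.90

_BED3 = ["chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    for c in _BED3:
        if c not in df.columns:
            raise FormatError(f"{what}: missing column {c!r}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise FormatError(f"{what}: need 0 <= start < end")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# element definition
# ---------------------------------------------------------------------------

def define_promoters(tss: pd.DataFrame, h3k4me3_peaks: pd.DataFrame) -> pd.DataFrame:
    """Promoters: +/- 1 kb of a TSS overlapping an H3K4me3 peak by >= 1 bp.

    ``tss`` needs columns chrom, pos (the strand-aware 5' transcript end)
    and gene; genes with several TSS yield several promoter records.  The
    result reports the number of TSS dropped for lacking a peak in
    ``df.attrs['n_dropped']``.
    """
    for c in ("chrom", "pos", "gene"):
        if c not in tss.columns:
            raise FormatError(f"TSS table: missing column {c!r}")
    peaks = _check_intervals(h3k4me3_peaks, "H3K4me3 peaks")
    missing = set(tss["chrom"]) - set(peaks["chrom"])
    if missing and len(set(tss["chrom"]) & set(peaks["chrom"])) == 0:
        raise FormatError(
            f"chromosome naming mismatch between TSS and peaks: {sorted(missing)}"
        )
    rows = []
    n_drop = 0
    for _, t in tss.iterrows():
        start = max(0, int(t["pos"]) - PROMOTER_FLANK)
        end = int(t["pos"]) + PROMOTER_FLANK
        p = peaks[peaks["chrom"] == t["chrom"]]
        if np.any((p["start"] < end) & (p["end"] > start)):
            rows.append(
                dict(chrom=t["chrom"], start=start, end=end,
                     id=f"P:{t['gene']}:{int(t['pos'])}", cls=PROMOTER,
                     gene=t["gene"], tss=int(t["pos"]))
            )
        else:
            n_drop += 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "cls", "gene", "tss"])
    out.attrs["n_dropped"] = n_drop
    return out


def merge_close(peaks: pd.DataFrame, gap: int = MERGE_GAP) -> pd.DataFrame:
    """Merge intervals whose gap is strictly less than ``gap`` bp.

    Bookended or overlapping intervals (gap <= 0) always merge.
    """
    peaks = _check_intervals(peaks, "peaks")
    rows = []
    for chrom, g in peaks.groupby("chrom", sort=True):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e < gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=_BED3)


def define_res(h3k27ac_peaks: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Build the master regulatory-element list for one condition.

    Ordered pipeline: (1) merge H3K27ac peaks with gap < 500 bp; (2) discard
    merged peaks shorter than 500 bp; (3) discard peaks overlapping any
    promoter; (4) master list = surviving intergenic peaks + promoters.
    """
    merged = merge_close(h3k27ac_peaks, MERGE_GAP)
    merged = merged[(merged["end"] - merged["start"]) >= MIN_PEAK_LEN]
    keep = []
    for _, r in merged.iterrows():
        p = promoters[promoters["chrom"] == r["chrom"]]
        if not np.any((p["start"] < r["end"]) & (p["end"] > r["start"])):
            keep.append(r)
    res = pd.DataFrame(keep, columns=_BED3).reset_index(drop=True)
    res["id"] = [f"E:{c}:{s}-{e}" for c, s, e in res[_BED3].itertuples(index=False)]
    res["cls"] = INTERGENIC
    master = pd.concat(
        [res, promoters[["chrom", "start", "end", "id", "cls"]]], ignore_index=True
    )
    return _check_intervals(master, "master RE list")


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def score_activity(res: pd.DataFrame, signal: pd.DataFrame) -> pd.DataFrame:
    """Mean per-base signal over each element (bedGraph-style input).

    ``signal`` has columns chrom, start, end, value (non-covered bases count
    as 0).  Elements with zero coverage score 0 with a logged warning.
    """
    sig = _check_intervals(signal, "signal")
    if "value" not in sig.columns:
        raise FormatError("signal: missing column 'value'")
    out = res.copy()
    acts = np.zeros(len(res))
    for chrom, g in sig.groupby("chrom"):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        vals = g["value"].to_numpy(dtype=float)
        sel = res["chrom"] == chrom
        for i in np.flatnonzero(sel.to_numpy()):
            s, e = int(res["start"].iloc[i]), int(res["end"].iloc[i])
            ov = np.minimum(ends, e) - np.maximum(starts, s)
            ov = np.clip(ov, 0, None)
            acts[i] = float(np.dot(ov, vals)) / (e - s)
    uncovered = ~res["chrom"].isin(sig["chrom"])
    if uncovered.any():
        log.warning("%d element(s) on chromosomes without signal; activity 0",
                    int(uncovered.sum()))
    out["activity"] = acts
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Sparse symmetric intra-chromosomal contact matrix at fixed bin size."""

    bin_size: int
    chrom_sizes: dict[str, int]
    triplets: pd.DataFrame  # chrom, bin_i, bin_j, value (upper triangle)
    normalization: str = "raw"
    _decay: tuple[float, float] | None = field(default=None, repr=False)
    _cov_cut: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        t = self.triplets
        for c in ("chrom", "bin_i", "bin_j", "value"):
            if c not in t.columns:
                raise FormatError(f"contact triplets: missing column {c!r}")
        if (t["value"] < 0).any():
            raise FormatError("contact values must be >= 0")
        i, j = t["bin_i"].to_numpy(), t["bin_j"].to_numpy()
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        t = t.assign(bin_i=lo, bin_j=hi)
        t = t.groupby(["chrom", "bin_i", "bin_j"], as_index=False)["value"].sum()
        for chrom, g in t.groupby("chrom"):
            n_bins = self.n_bins(chrom)
            if (g["bin_j"] >= n_bins).any():
                raise FormatError(f"{chrom}: bin index beyond chromosome length")
        self.triplets = t
        self._lookup = {
            (c, int(a), int(b)): float(v)
            for c, a, b, v in t.itertuples(index=False)
        }

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)

    def value(self, chrom: str, i: int, j: int) -> float:
        a, b = (i, j) if i <= j else (j, i)
        return self._lookup.get((chrom, a, b), 0.0)

    def bin_coverage(self, chrom: str) -> np.ndarray:
        """Marginal coverage (row sums) per bin."""
        n = self.n_bins(chrom)
        cov = np.zeros(n)
        g = self.triplets[self.triplets["chrom"] == chrom]
        np.add.at(cov, g["bin_i"].to_numpy(), g["value"].to_numpy())
        off = g["bin_i"].to_numpy() != g["bin_j"].to_numpy()
        np.add.at(cov, g["bin_j"].to_numpy()[off], g["value"].to_numpy()[off])
        return cov

    # -- distance decay ----------------------------------------------------

    def mean_contact_by_distance(
        self, d_min: int = 10_000, d_max: int = SEARCH_RADIUS
    ) -> pd.DataFrame:
        """Genome-average contact per bin-distance over [d_min, d_max]."""
        s_min = max(1, d_min // self.bin_size)
        s_max = d_max // self.bin_size
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for chrom in self.chrom_sizes:
            n = self.n_bins(chrom)
            g = self.triplets[self.triplets["chrom"] == chrom]
            sep = (g["bin_j"] - g["bin_i"]).to_numpy()
            val = g["value"].to_numpy()
            for s in range(s_min, min(s_max, n - 1) + 1):
                sums[s] = sums.get(s, 0.0) + float(val[sep == s].sum())
                counts[s] = counts.get(s, 0) + (n - s)  # all pairs, zeros included
        rows = [
            (s * self.bin_size, sums.get(s, 0.0) / counts[s])
            for s in sorted(counts)
            if counts[s] > 0
        ]
        return pd.DataFrame(rows, columns=["distance", "mean_contact"])


def read_contacts(triplet_path, header_path) -> ContactMatrix:
    """Read a TSV triplet matrix with its JSON header sidecar."""
    with open(header_path) as fh:
        hdr = json.load(fh)
    t = pd.read_csv(triplet_path, sep="\t", float_precision="round_trip")
    return ContactMatrix(
        bin_size=int(hdr["bin_size"]),
        chrom_sizes={k: int(v) for k, v in hdr["chrom_sizes"].items()},
        triplets=t,
        normalization=hdr.get("normalization", "raw"),
    )


def write_contacts(cm: ContactMatrix, triplet_path, header_path) -> None:
    cm.triplets.to_csv(triplet_path, sep="\t", index=False, float_format="%.17g")
    with open(header_path, "w") as fh:
        json.dump(
            dict(bin_size=cm.bin_size, chrom_sizes=cm.chrom_sizes,
                 normalization=cm.normalization),
            fh, indent=1,
        )


def fit_gamma(
    cm: ContactMatrix, d_min: int = 10_000, d_max: int = SEARCH_RADIUS
) -> tuple[float, float]:
    """Power-law decay exponent gamma of contact frequency with distance.

    Least-squares fit of log(mean contact) on log(distance); returns
    (gamma, log_amplitude) so the fitted curve is
    ``exp(log_amplitude) * d**(-gamma)``.
    """
    decay = cm.mean_contact_by_distance(d_min, d_max)
    decay = decay[decay["mean_contact"] > 0]
    if len(decay) < 10:
        raise InsufficientDataError(
            f"need >= 10 distance bins with positive mean contact, got {len(decay)}"
        )
    x = np.log(decay["distance"].to_numpy())
    y = np.log(decay["mean_contact"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    return float(-slope), float(intercept)


def get_contact(
    cm: ContactMatrix,
    chrom: str,
    pos_p: int,
    pos_r: int,
    gamma: float | None = None,
    log_amp: float | None = None,
    coverage_quantile: float = 0.05,
) -> float:
    """Contact between two positions, imputing poorly covered bin pairs.

    A pair is poorly covered when either anchoring bin's marginal coverage
    falls below the ``coverage_quantile`` of its chromosome's bins; the
    imputed value is the fitted power-law expectation at the pair's
    distance (anchored to the matrix's own distance-decay curve).
    """
    if gamma is None or log_amp is None:
        if cm._decay is None:
            cm._decay = fit_gamma(cm)
        gamma, log_amp = cm._decay
    i, j = pos_p // cm.bin_size, pos_r // cm.bin_size
    key = chrom
    if key not in cm._cov_cut:
        cov = cm.bin_coverage(chrom)
        cm._cov_cut[key] = float(np.quantile(cov, coverage_quantile))
        cm._cov_cache = getattr(cm, "_cov_cache", {})
        cm._cov_cache[key] = cov
    cov = cm._cov_cache[key]
    cut = cm._cov_cut[key]
    d = abs(pos_r - pos_p)
    if cov[i] <= cut or cov[j] <= cut:
        d_eff = max(d, cm.bin_size)  # power law diverges at d = 0
        return float(np.exp(log_amp) * d_eff ** (-gamma))
    return cm.value(chrom, i, j)


# ---------------------------------------------------------------------------
# scoring and link calling
# ---------------------------------------------------------------------------

def abc_scores(
    promoters: pd.DataFrame,
    res_with_activity: pd.DataFrame,
    cm: ContactMatrix,
    condition: str = "WT",
    coverage_quantile: float = 0.05,
) -> pd.DataFrame:
    """Score all promoter-element pairs within the 5 Mb search radius.

    One row per (promoter, element) pair with activity, contact, distance,
    and the normalized ABC score; scores of one promoter's candidate set
    sum to 1.  Promoters whose candidate activity x contact sum is zero are
    skipped with a warning.  Trans (different-chromosome) pairs are never
    candidates.  The promoter's own element is excluded from its candidate
    set.
    """
    gamma, log_amp = fit_gamma(cm)
    rows = []
    for _, p in promoters.iterrows():
        p_mid = (int(p["start"]) + int(p["end"])) // 2
        cand = res_with_activity[res_with_activity["chrom"] == p["chrom"]].copy()
        cand = cand[cand["id"] != p["id"]]
        mids = ((cand["start"] + cand["end"]) // 2).to_numpy()
        dist = np.abs(mids - p_mid)
        cand = cand[dist <= SEARCH_RADIUS]
        mids = mids[dist <= SEARCH_RADIUS]
        if cand.empty:
            continue
        contacts = np.array(
            [
                get_contact(cm, p["chrom"], p_mid, int(m), gamma, log_amp,
                            coverage_quantile)
                for m in mids
            ]
        )
        weights = cand["activity"].to_numpy() * contacts
        denom = weights.sum()
        if denom <= 0:
            log.warning("promoter %s: zero activity x contact denominator; skipped",
                        p["id"])
            continue
        score = weights / denom
        for (_, r), c, s, m in zip(cand.iterrows(), contacts, score, mids):
            rows.append(
                dict(
                    promoter_id=p["id"], promoter_pos=p_mid, re_id=r["id"],
                    re_cls=r["cls"], chrom=p["chrom"], activity=r["activity"],
                    contact=c, distance=int(abs(m - p_mid)), abc=s,
                    condition=condition,
                    link_id=f"{p['id']}|{r['id']}|{p_mid}",
                )
            )
    return pd.DataFrame(rows)


def call_links(
    links_by_condition: dict[str, pd.DataFrame],
    quantile: float = STRONG_QUANTILE,
) -> tuple[pd.DataFrame, float]:
    """Select strong links at the pooled score quantile and categorize them.

    The threshold is the ``quantile`` (default 90th percentile) of the ABC
    scores pooled over all conditions; links with score >= threshold are
    strong (ties kept, so the strong set may slightly exceed the nominal
    decile).  Link IDs are matched across conditions: a link found above
    threshold in every condition is 'common', otherwise '<condition>-unique'.
    Returns (strong link table with a 'category' column, threshold).
    """
    pooled = pd.concat(
        [df.assign(condition=c) for c, df in links_by_condition.items()],
        ignore_index=True,
    )
    if pooled.empty:
        raise InsufficientDataError("no links to threshold")
    thr = float(np.quantile(pooled["abc"].to_numpy(), quantile))
    strong = pooled[pooled["abc"] >= thr].copy()
    by_cond = {
        c: set(strong.loc[strong["condition"] == c, "link_id"]) for c in links_by_condition
    }
    common = set.intersection(*by_cond.values()) if by_cond else set()

    def cat(row):
        return "common" if row["link_id"] in common else f"{row['condition']}-unique"

    strong["category"] = strong.apply(cat, axis=1)
    return strong, thr


def link_lengths(strong: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category genomic-distance distributions and rank location tests.

    Returns (summary with n/median/mean per category, pairwise two-sided
    Mann-Whitney U tests).  Categories with fewer than two links are
    skipped with a warning.
    """
    summaries, tests = [], []
    groups = {}
    # a common link appears once per condition; count each link ID once
    strong = strong.drop_duplicates(subset=["link_id", "category"])
    for cat, g in strong.groupby("category"):
        if len(g) < 2:
            log.warning("category %s has < 2 links; skipped", cat)
            continue
        d = g["distance"].to_numpy()
        groups[cat] = d
        summaries.append(
            dict(category=cat, n=len(d), median=float(np.median(d)),
                 mean=float(np.mean(d)))
        )
    cats = sorted(groups)
    for a in range(len(cats)):
        for b in range(a + 1, len(cats)):
            u = stats.mannwhitneyu(groups[cats[a]], groups[cats[b]],
                                   alternative="two-sided")
            tests.append(
                dict(category_a=cats[a], category_b=cats[b],
                     statistic=float(u.statistic), p_value=float(u.pvalue))
            )
    return pd.DataFrame(summaries), pd.DataFrame(tests)


def enrichment_chi2(
    strong: pd.DataFrame, regulation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Chi-square enrichment of link categories against gene regulation.

    ``regulation`` maps genes to labels (columns gene, label, e.g.
    up/down/unchanged); each strong link is associated with its promoter's
    gene.  Returns (observed contingency, per-cell fold enrichment
    observed/expected, chi2 statistic, p value); degrees of freedom are
    (R-1)(C-1).  A warning recommends an exact test when an expected cell
    count falls below 1.
    """
    gene_of = dict(zip(regulation["gene"], regulation["label"]))
    links = strong.copy()
    links["gene"] = links["promoter_id"].str.split(":").str[1]
    links = links[links["gene"].isin(gene_of)]
    if links.empty:
        raise InsufficientDataError("no links map to a regulated gene")
    links["label"] = links["gene"].map(gene_of)
    table = pd.crosstab(links["category"], links["label"])
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    if (expected < 1).any():
        log.warning("expected cell count < 1; consider an exact test")
    fold = pd.DataFrame(table.to_numpy() / expected, index=table.index,
                        columns=table.columns)
    return table, fold, float(chi2), float(p)


# ---------------------------------------------------------------------------
# BED / bedGraph plumbing
# ---------------------------------------------------------------------------

def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = names or (_BED3 + ["id", "score", "strand"])[: df.shape[1]]
    df.columns = cols[: df.shape[1]]
    return _check_intervals(df, str(path))


def write_bed(df: pd.DataFrame, path, score_col: str | None = None) -> None:
    """Write BED; a float score column is scaled x1000 and rounded to fit
    the BED score convention (pair with a full-precision TSV sidecar)."""
    out = df.copy()
    cols = _BED3 + [c for c in ("id",) if c in out.columns]
    if score_col is not None:
        out["score"] = np.round(out[score_col] * 1000).astype(int)
        cols += ["score"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=_BED3 + ["value"])
    return _check_intervals(df, str(path))
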