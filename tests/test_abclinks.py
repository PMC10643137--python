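"""ABC link scoring: element definition, activity, contacts, thresholds."""

import numpy as np
import pandas as pd
import pytest

from chromodyn import abclinks as ab
from chromodyn.exceptions import FormatError, InsufficientDataError
from chromodyn.toygenome import make_toy_genome, power_law_contacts


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestDefinePromoters:
    def test_tss_with_overlapping_peak_kept(self):
        tss = pd.DataFrame({"chrom": ["c"], "pos": [10_000], "gene": ["g"]})
        peaks = _bed([("c", 9_500, 9_600)])
        out = ab.define_promoters(tss, peaks)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (9_000, 11_000)

    def test_tss_without_peak_dropped_and_counted(self):
        tss = pd.DataFrame({"chrom": ["c"] * 2, "pos": [10_000, 50_000],
                            "gene": ["g1", "g2"]})
        peaks = _bed([("c", 9_500, 9_600)])
        out = ab.define_promoters(tss, peaks)
        assert len(out) == 1 and out.attrs["n_dropped"] == 1

    def test_matches_quadratic_overlap_oracle(self, rng):
        tss = pd.DataFrame({
            "chrom": "c", "pos": rng.integers(2_000, 100_000, 30),
            "gene": [f"g{i}" for i in range(30)],
        })
        peaks = _bed([("c", int(s), int(s + rng.integers(50, 3_000)))
                      for s in rng.integers(0, 100_000, 15)])
        out = ab.define_promoters(tss, peaks)
        kept = set(out["gene"])
        for _, t in tss.iterrows():
            s, e = t["pos"] - 1_000, t["pos"] + 1_000
            hit = any(
                max(s, p["start"]) < min(e, p["end"]) for _, p in peaks.iterrows()
            )
            assert (t["gene"] in kept) == hit

    def test_chromosome_mismatch_raises(self):
        tss = pd.DataFrame({"chrom": ["c1"], "pos": [10_000], "gene": ["g"]})
        with pytest.raises(FormatError, match="c1"):
            ab.define_promoters(tss, _bed([("c2", 0, 100)]))


class TestDefineRes:
    def test_close_peaks_merged_and_kept(self):
        # gap 400 < 500 -> merged to length 1300 >= 500 -> kept
        proms = ab.define_promoters(
            pd.DataFrame({"chrom": ["c"], "pos": [50_000], "gene": ["g"]}),
            _bed([("c", 49_900, 50_100)]),
        )
        out = ab.define_res(_bed([("c", 0, 400), ("c", 800, 1_300)]), proms)
        inter = out[out["cls"] == "intergenic_re"]
        assert len(inter) == 1
        assert (inter["start"].iloc[0], inter["end"].iloc[0]) == (0, 1_300)

    def test_short_lone_peak_discarded(self):
        proms = ab.define_promoters(
            pd.DataFrame({"chrom": ["c"], "pos": [50_000], "gene": ["g"]}),
            _bed([("c", 49_900, 50_100)]),
        )
        out = ab.define_res(_bed([("c", 0, 450)]), proms)
        assert (out["cls"] == "intergenic_re").sum() == 0

    def test_bookended_peaks_always_merge(self):
        merged = ab.merge_close(_bed([("c", 0, 300), ("c", 300, 700)]), gap=500)
        assert len(merged) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        size = 100_000
        peaks = _bed(sorted(
            (("c", int(s), int(s + rng.integers(100, 1_500)))
             for s in rng.integers(0, size - 2_000, 20)),
            key=lambda r: r[1],
        ))
        proms = pd.DataFrame({
            "chrom": "c",
            "start": [20_000, 60_000, 80_000],
            "end": [22_000, 62_000, 82_000],
            "id": ["P:a:21000", "P:b:61000", "P:c:81000"],
            "cls": "promoter",
        })
        out = ab.define_res(peaks, proms)
        got = set(
            map(tuple, out.loc[out["cls"] == "intergenic_re",
                               ["start", "end"]].to_numpy())
        )
        # brute force: per-base paint, merge at gap < 500, filter, overlap
        cover = np.zeros(size, dtype=bool)
        for _, p in peaks.iterrows():
            cover[p["start"]:p["end"]] = True
        # merge: close gaps strictly shorter than 500
        merged = []
        i = 0
        while i < size:
            if cover[i]:
                j = i
                while j < size:
                    if cover[j]:
                        j += 1
                    else:
                        nxt = j
                        while nxt < size and not cover[nxt] and nxt - j < 500:
                            nxt += 1
                        if nxt < size and cover[nxt] and nxt - j < 500:
                            j = nxt
                        else:
                            break
                merged.append((i, j))
                i = j
            else:
                i += 1
        want = set()
        for s, e in merged:
            if e - s < 500:
                continue
            if any(max(s, ps) < min(e, pe)
                   for ps, pe in proms[["start", "end"]].to_numpy()):
                continue
            want.add((s, e))
        assert got == want


class TestActivity:
    def _re(self, s, e):
        return pd.DataFrame({"chrom": ["c"], "start": [s], "end": [e],
                             "id": ["E:x"], "cls": ["intergenic_re"]})

    def test_uniform_signal(self):
        sig = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1_000],
                            "value": [2.0]})
        out = ab.score_activity(self._re(0, 1_000), sig)
        assert out["activity"].iloc[0] == pytest.approx(2.0)

    def test_half_covered_mean(self):
        sig = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [500],
                            "value": [4.0]})
        out = ab.score_activity(self._re(0, 1_000), sig)
        assert out["activity"].iloc[0] == pytest.approx(2.0)

    def test_matches_per_base_oracle(self, rng):
        edges = np.sort(rng.choice(np.arange(1, 5_000), 30, replace=False))
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [5_000]])
        vals = rng.uniform(0, 5, len(starts))
        sig = pd.DataFrame({"chrom": "c", "start": starts, "end": ends,
                            "value": vals})
        re_s, re_e = 1_234, 4_321
        out = ab.score_activity(self._re(re_s, re_e), sig)
        base = np.zeros(5_000)
        for s, e, v in zip(starts, ends, vals):
            base[s:e] = v
        assert out["activity"].iloc[0] == pytest.approx(base[re_s:re_e].mean())


class TestContacts:
    def test_gamma_exact_on_constructed_matrix(self):
        cm = power_law_contacts("c", 2_000_000, gamma=1.0, amplitude=100.0)
        g, _ = ab.fit_gamma(cm)
        assert g == pytest.approx(1.0, abs=1e-6)

    def test_gamma_zero_for_constant(self):
        cm = power_law_contacts("c", 2_000_000, gamma=0.0, amplitude=5.0)
        g, _ = ab.fit_gamma(cm)
        assert g == pytest.approx(0.0, abs=1e-9)

    def test_gamma_with_poisson_noise(self):
        cm = power_law_contacts("c", 3_000_000, gamma=1.0, amplitude=2e5,
                                poisson_noise=True,
                                rng=np.random.default_rng(9))
        g, _ = ab.fit_gamma(cm)
        assert g == pytest.approx(1.0, abs=0.05)

    def test_well_covered_pair_verbatim(self):
        cm = power_law_contacts("c", 500_000, gamma=1.0)
        gam, amp = ab.fit_gamma(cm, d_min=5_000, d_max=400_000)
        # central bins, well away from the low-coverage matrix edges
        v = ab.get_contact(cm, "c", 202_500, 242_500, gam, amp)
        assert v == cm.value("c", 40, 48)

    def test_zero_coverage_bin_imputed_from_power_law(self):
        cm = power_law_contacts("c", 500_000, gamma=1.0, amplitude=100.0)
        # erase one bin's contacts entirely
        t = cm.triplets
        killed = 37
        t = t[(t["bin_i"] != killed) & (t["bin_j"] != killed)]
        cm2 = ab.ContactMatrix(cm.bin_size, cm.chrom_sizes, t)
        gam, amp = ab.fit_gamma(cm2, d_min=5_000, d_max=400_000)
        pos_p = killed * 5_000 + 2_500
        pos_r = (killed + 11) * 5_000 + 2_500
        v = ab.get_contact(cm2, "c", pos_p, pos_r, gam, amp)
        d = abs(pos_r - pos_p)
        assert v == pytest.approx(np.exp(amp) * d ** (-gam))

    def test_imputation_continuous_in_distance(self):
        cm = power_law_contacts("c", 500_000, gamma=1.0, amplitude=100.0)
        gam, amp = ab.fit_gamma(cm, d_min=5_000, d_max=400_000)
        ds = np.arange(10_000, 200_000, 5_000)
        vals = [np.exp(amp) * d ** (-gam) for d in ds]
        rel_steps = np.abs(np.diff(vals)) / np.array(vals[:-1])
        # no jump exceeds the local slope of the fitted curve
        expected = 1 - (ds[1:] / ds[:-1]) ** (-gam)
        assert np.all(rel_steps <= expected + 1e-9)


class TestAbcScores:
    def _setup(self, activities, contacts_const=True):
        proms = pd.DataFrame({
            "chrom": ["c"], "start": [99_000], "end": [101_000],
            "id": ["P:g:100000"], "cls": ["promoter"], "gene": ["g"],
            "tss": [100_000],
        })
        res = pd.DataFrame({
            "chrom": "c",
            "start": [200_000, 300_000],
            "end": [201_000, 301_000],
            "id": ["E:1", "E:2"],
            "cls": "intergenic_re",
            "activity": activities,
        })
        return proms, res

    def test_hand_evaluated_equation(self, monkeypatch):
        # A = (3, 1), C = (2, 2) -> scores (0.75, 0.25)
        proms, res = self._setup([3.0, 1.0])
        cm = power_law_contacts("c", 400_000, gamma=0.0, amplitude=2.0)
        links = ab.abc_scores(proms, res, cm)
        assert links["abc"].tolist() == pytest.approx([0.75, 0.25])

    def test_single_candidate_scores_one(self):
        proms, res = self._setup([3.0, 1.0])
        res = res.iloc[:1]
        cm = power_law_contacts("c", 400_000, gamma=0.0, amplitude=2.0)
        links = ab.abc_scores(proms, res, cm)
        assert links["abc"].iloc[0] == pytest.approx(1.0)

    def test_invariant_under_activity_rescaling(self):
        proms, res = self._setup([3.0, 1.0])
        cm = power_law_contacts("c", 400_000, gamma=1.0, amplitude=50.0)
        s1 = ab.abc_scores(proms, res, cm)["abc"].to_numpy()
        res2 = res.assign(activity=res["activity"] * 17.3)
        s2 = ab.abc_scores(proms, res2, cm)["abc"].to_numpy()
        assert s1 == pytest.approx(s2)


class TestCallLinks:
    def _links(self, scores, cond, ids=None):
        n = len(scores)
        return pd.DataFrame({
            "promoter_id": [f"P:{i}" for i in range(n)],
            "promoter_pos": np.arange(n) * 10_000,
            "re_id": [f"E:{i}" for i in range(n)],
            "re_cls": "intergenic_re",
            "chrom": "c",
            "activity": 1.0,
            "contact": 1.0,
            "distance": (np.arange(n) + 1) * 50_000,
            "abc": scores,
            "condition": cond,
            "link_id": ids if ids is not None else [f"L{i}" for i in range(n)],
        })

    def test_top_decile_of_ten_is_one(self):
        links = self._links(np.round(np.arange(0.01, 0.11, 0.01), 2), "WT")
        strong, thr = ab.call_links({"WT": links})
        assert len(strong) == 1
        assert strong["abc"].iloc[0] == pytest.approx(0.10)

    def test_shared_link_is_common(self):
        wt = self._links([0.9] + [0.01 * i for i in range(1, 9)], "WT",
                         ids=["L0"] + [f"W{i}" for i in range(8)])
        ko = self._links([0.88] + [0.01 * i for i in range(1, 9)], "KO",
                         ids=["L0"] + [f"K{i}" for i in range(8)])
        strong, thr = ab.call_links({"WT": wt, "KO": ko})
        cats = dict(zip(strong["link_id"], strong["category"]))
        assert cats["L0"] == "common"

    def test_categories_match_set_algebra_oracle(self, rng):
        ids_wt = [f"L{i}" for i in rng.choice(200, 120, replace=False)]
        ids_ko = [f"L{i}" for i in rng.choice(200, 120, replace=False)]
        wt = self._links(rng.random(120), "WT", ids=ids_wt)
        ko = self._links(rng.random(120), "KO", ids=ids_ko)
        strong, thr = ab.call_links({"WT": wt, "KO": ko})
        s_wt = {l for l, c in zip(wt["link_id"], wt["abc"]) if c >= thr}
        s_ko = {l for l, c in zip(ko["link_id"], ko["abc"]) if c >= thr}
        for _, row in strong.iterrows():
            want = (
                "common" if row["link_id"] in (s_wt & s_ko)
                else f"{row['condition']}-unique"
            )
            assert row["category"] == want

    def test_empty_pool_raises(self):
        with pytest.raises(InsufficientDataError):
            ab.call_links({"WT": pd.DataFrame(columns=["abc", "link_id",
                                                       "condition"])})


class TestLinkLengths:
    def test_separated_categories_detected(self, rng):
        rows = []
        for i in range(100):
            rows.append(("WT-unique", 2_000_000 + int(rng.integers(-5e4, 5e4))))
            rows.append(("KO-unique", 1_000_000 + int(rng.integers(-5e4, 5e4))))
        df = pd.DataFrame(rows, columns=["category", "distance"])
        df["link_id"] = [f"L{i}" for i in range(len(df))]
        summary, tests = ab.link_lengths(df)
        med = dict(zip(summary["category"], summary["median"]))
        assert med["WT-unique"] > med["KO-unique"]
        assert tests["p_value"].iloc[0] < 1e-6
        # medians equal brute-force medians
        for cat in ("WT-unique", "KO-unique"):
            assert med[cat] == np.median(df.loc[df["category"] == cat,
                                                "distance"])

    def test_identical_distributions_mostly_nonsignificant(self):
        n_sig = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            df = pd.DataFrame({
                "category": ["WT-unique"] * 50 + ["KO-unique"] * 50,
                "distance": rng.integers(1e5, 2e6, 100),
            })
            df["link_id"] = [f"L{i}" for i in range(100)]
            _, tests = ab.link_lengths(df)
            n_sig += tests["p_value"].iloc[0] < 0.05
        assert n_sig <= 2  # >= 90% non-significant


class TestEnrichment:
    def _strong(self, table):
        rows = []
        i = 0
        for cat, genes in table.items():
            for gene, count in genes.items():
                for _ in range(count):
                    rows.append({
                        "promoter_id": f"P:{gene}:1", "category": cat,
                        "link_id": f"L{i}",
                    })
                    i += 1
        return pd.DataFrame(rows)

    def test_2x2_closed_form(self):
        # [[30, 10], [10, 30]] -> chi2 = n(ad-bc)^2 / (row/col products) = 20
        strong = self._strong({
            "WT-unique": {"up": 30, "down": 10},
            "KO-unique": {"up": 10, "down": 30},
        })
        reg = pd.DataFrame({"gene": ["up", "down"], "label": ["up", "down"]})
        table, fold, chi2, p = ab.enrichment_chi2(strong, reg)
        n, a, b, c, d = 80, 30, 10, 10, 30
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed) and closed == 20.0

    def test_independent_margins_fold_one(self):
        strong = self._strong({
            "WT-unique": {"up": 40, "down": 20},
            "KO-unique": {"up": 20, "down": 10},
        })
        reg = pd.DataFrame({"gene": ["up", "down"], "label": ["up", "down"]})
        _, fold, chi2, _ = ab.enrichment_chi2(strong, reg)
        assert np.allclose(fold.to_numpy(), 1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_row_swap_invariance(self):
        t1 = self._strong({
            "WT-unique": {"up": 30, "down": 10},
            "KO-unique": {"up": 12, "down": 28},
        })
        t2 = self._strong({
            "KO-unique": {"up": 12, "down": 28},
            "WT-unique": {"up": 30, "down": 10},
        })
        reg = pd.DataFrame({"gene": ["up", "down"], "label": ["up", "down"]})
        assert ab.enrichment_chi2(t1, reg)[2] == pytest.approx(
            ab.enrichment_chi2(t2, reg)[2]
        )


class TestEndToEnd:
    def test_planted_pairs_rank_top(self):
        # high activity x high contact planted at specific pairs makes those
        # pairs the top-ranked links
        g = make_toy_genome(seed=21, n_planted=0)
        proms = ab.define_promoters(g.tss, g.h3k4me3)
        res = ab.define_res(g.h3k27ac["WT"], proms)
        res = ab.score_activity(res, g.signal["WT"])
        # plant: boost contact between first promoter and one far element
        p = proms.iloc[0]
        p_mid = (p["start"] + p["end"]) // 2
        inter = res[res["cls"] == "intergenic_re"]
        far = inter.iloc[(np.abs(
            (inter["start"] + inter["end"]) // 2 - p_mid
        )).to_numpy().argsort()[-5]]
        r_mid = (far["start"] + far["end"]) // 2
        cm = power_law_contacts(
            g.chrom, g.size, gamma=1.0, amplitude=100.0,
            planted_pairs=[(p_mid // 5_000, r_mid // 5_000)],
            planted_boost=500.0,
        )
        res.loc[res["id"] == far["id"], "activity"] = res["activity"].max() * 10
        links = ab.abc_scores(proms, res, cm)
        mine = links[links["promoter_id"] == p["id"]]
        assert mine.sort_values("abc", ascending=False)["re_id"].iloc[0] == far["id"]

    def test_roundtrip_contact_matrix(self, tmp_path):
        cm = power_law_contacts("c", 200_000, gamma=1.0)
        ab.write_contacts(cm, tmp_path / "m.tsv", tmp_path / "m.json")
        back = ab.read_contacts(tmp_path / "m.tsv", tmp_path / "m.json")
        assert back.bin_size == cm.bin_size
        assert back.value("c", 3, 17) == cm.value("c", 3, 17)
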