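"""LDA-effect-size screen and cross-site direction-of-change concordance."""

import numpy as np
import pytest

from gyntransloc import (
    AbundanceTable,
    CohortError,
    CohortParams,
    direction_of_change,
    lefse_lite,
    to_relative,
)
from gyntransloc.synthetic import expected_tables


def planted_table(fold=10.0, n_per_group=20, n_taxa=50, n_planted=3,
                  cv=0.1, seed=0):
    """Relative table with `n_planted` taxa at a `fold` ratio between groups,
    multiplicative noise with the given CV, plus labels."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 1.5, size=n_taxa)
    cols, ids, labels = [], [], {}
    for g, gname in enumerate(["g1", "g2"]):
        for k in range(n_per_group):
            mean = base.copy()
            if g == 1:
                mean[:n_planted] *= fold
            col = mean * np.exp(rng.normal(0, cv, size=n_taxa))
            cols.append(col / col.sum())
            sid = f"{gname}_{k}"
            ids.append(sid)
            labels[sid] = gname
    tab = AbundanceTable([f"T{i}" for i in range(n_taxa)], ids,
                         np.column_stack(cols), "relative")
    return tab, labels


class TestLefseLite:
    def test_planted_tenfold_taxa_flagged(self):
        tab, labels = planted_table(fold=10.0, seed=1)
        recs = lefse_lite(tab, labels, seed=2)
        by_taxon = {r.taxon: r for r in recs}
        for t in ("T0", "T1", "T2"):
            assert by_taxon[t].passes
            assert abs(by_taxon[t].lda_log10) > 3.0
            assert by_taxon[t].enriched_group == "g2"

    def test_duplicated_groups_pass_nothing(self):
        tab, _ = planted_table(fold=1.0, n_per_group=10, seed=3)
        # two "groups" that are exact copies of the same columns
        vals = np.hstack([tab.values[:, :10], tab.values[:, :10]])
        ids = [f"a{k}" for k in range(10)] + [f"b{k}" for k in range(10)]
        dup = AbundanceTable(list(tab.taxon_ids), ids, vals, "relative")
        labels = {s: s[0] for s in ids}
        recs = lefse_lite(dup, labels, seed=4)
        assert not any(r.kw_p < 0.05 for r in recs)
        assert not any(r.passes for r in recs)

    def test_shuffled_null_passes_nothing(self):
        # many taxa of modest abundance: on the per-million scale a null
        # mean-difference stays far below the 10^3 effect gate
        tab, labels = planted_table(fold=1.0, n_taxa=200, seed=5)
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(10):
            shuffled = dict(zip(labels, rng.permutation(list(labels.values()))))
            recs = lefse_lite(tab, shuffled, seed=rep)
            hits += any(r.passes for r in recs)
        assert hits <= 1  # the LDA gate blocks KW survivors in >= 90% of runs

    def test_sample_order_invariance(self):
        tab, labels = planted_table(seed=7)
        perm = np.random.default_rng(8).permutation(tab.n_samples)
        shuffled = tab.select_samples([tab.sample_ids[i] for i in perm])
        r1 = lefse_lite(tab, labels, seed=9)
        r2 = lefse_lite(shuffled, labels, seed=9)
        assert [(r.taxon, r.lda_log10) for r in r1] == \
            [(r.taxon, r.lda_log10) for r in r2]

    def test_power_monotone_in_fold(self):
        flagged = []
        for fold in (1, 2, 5, 10):
            tab, labels = planted_table(fold=fold, n_planted=5, seed=10)
            recs = lefse_lite(tab, labels, seed=11)
            flagged.append(sum(r.passes for r in recs[:5]))
        assert flagged == sorted(flagged)

    def test_more_than_two_groups_errors(self):
        tab, labels = planted_table(n_per_group=6, seed=12)
        labels = {s: ("g3" if s.endswith("_0") else g)
                  for s, g in labels.items()}
        with pytest.raises(CohortError, match="2 groups"):
            lefse_lite(tab, labels, seed=0)

    def test_small_group_errors(self):
        tab, labels = planted_table(n_per_group=2, seed=13)
        with pytest.raises(CohortError, match="at least 3"):
            lefse_lite(tab, labels, seed=0)

    def test_requires_relative_mode(self, small_counts):
        with pytest.raises(CohortError, match="relative"):
            lefse_lite(small_counts, {"s1": "a", "s2": "b"}, seed=0)


class TestDirectionOfChange:
    def two_col_table(self, healthy, disease, taxa=None):
        taxa = taxa or [f"T{i}" for i in range(len(healthy))]
        h = np.asarray(healthy, float)
        d = np.asarray(disease, float)
        vals = np.column_stack([h / h.sum(), d / d.sum()])
        return AbundanceTable(taxa, ["H", "D"], vals, "relative")

    def test_identical_site_tables_fully_concordant(self):
        tab = self.two_col_table([1, 2, 3], [3, 2, 1])
        labels = {"H": "healthy", "D": "endometritis"}
        res = direction_of_change(tab, tab, labels)
        nonzero = ~res.both_zero
        assert res.fraction == 1.0
        assert nonzero.sum() == res.n_total

    def test_single_taxon_sign_rule(self):
        u = self.two_col_table([0.5, 0.5], [0.6, 0.4], ["x", "pad"])
        v = self.two_col_table([0.5, 0.5], [0.3, 0.7], ["x", "pad"])
        labels = {"H": "healthy", "D": "endometritis"}
        res = direction_of_change(u, v, labels, ["x"])
        assert res.n_concordant == 0 and res.n_total == 1

    def test_missing_taxon_named(self):
        u = self.two_col_table([1, 2], [2, 1], ["x", "y"])
        v = self.two_col_table([1, 2], [2, 1], ["x", "z"])
        labels = {"H": "healthy", "D": "endometritis"}
        with pytest.raises(CohortError, match="'y'"):
            direction_of_change(u, v, labels, ["x", "y"])

    def test_noiseless_planted_effects_concordant(self):
        # effects planted on the vaginal source propagate to the uterus
        # through the mixture, so every direction agrees at zero noise
        effects = [(f"OTU{k + 2:04d}", "vagina", "endometritis",
                    (1.0 if k % 2 else -1.0))
                   for k in range(6)]
        params = CohortParams(n_subjects=4, n_taxa=30, pi_transloc=0.5,
                              effect_taxa=effects, seed=0)
        tu, tv, labels = expected_tables(params)
        res = direction_of_change(tu, tv, labels,
                                  [e[0] for e in effects])
        assert res.fraction == 1.0

    def test_half_opposed_gives_exactly_half(self):
        # uterus-endogenous effects opposite to vaginal ones for half the
        # taxa; pi = 0 decouples the sites so the signs are exact
        taxa = [f"OTU{k + 2:04d}" for k in range(8)]
        effects = []
        for k, t in enumerate(taxa):
            effects.append((t, "vagina", "endometritis", 1.0))
            u_sign = -2.0 if k < 4 else 2.0
            effects.append((t, "uterus", "endometritis", u_sign))
        params = CohortParams(n_subjects=4, n_taxa=40, pi_transloc=0.0,
                              effect_taxa=effects, seed=0)
        tu, tv, labels = expected_tables(params)
        res = direction_of_change(tu, tv, labels, taxa)
        assert res.n_concordant == 4 and res.n_total == 8
        assert res.fraction == 0.5
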