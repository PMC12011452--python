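"""Diet profiles: LCA collapsing, RRA conversion, pooling, derived tables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dietniche.io import (
    RANKS,
    GrowthFormMap,
    GrowthForm,
    Lineage,
    OtuTable,
    SampleRecord,
    Season,
    Species,
    TaxonAssignment,
    ValidationError,
    parse_lineage,
)
from dietniche.profiles import (
    DietProfile,
    growth_form_percentages,
    group_profiles,
    lca_collapse,
    pool_group_profile,
    resolve_taxa,
    to_rra,
    top_n_taxa,
)


def _profile(taxa, props, species=Species.SIKA_DEER, season=Season.SPRING):
    return DietProfile(species, season, "genus", taxa, np.array(props), 1)


class TestLcaCollapse:
    def test_congeneric_species_collapse_to_genus(self):
        a = TaxonAssignment(
            "OTU1",
            [
                parse_lineage("Rosaceae;Rubus;Rubus hirsutus"),
                parse_lineage("Rosaceae;Rubus;Rubus corchorifolius"),
            ],
        )
        lca = lca_collapse(a)
        assert lca.deepest_rank == "genus"
        assert lca.get("genus") == "Rubus"

    def test_single_candidate_kept_at_species(self):
        a = TaxonAssignment("OTU2", [parse_lineage("Smilacaceae;Smilax;Smilax china")])
        assert lca_collapse(a).get("species") == "Smilax china"

    def test_cross_family_collapse_to_order(self):
        a = TaxonAssignment(
            "OTU3",
            [
                parse_lineage("k__Plantae;p__Tracheophyta;c__Liliopsida;o__Poales;f__Poaceae;g__Poa"),
                parse_lineage("k__Plantae;p__Tracheophyta;c__Liliopsida;o__Poales;f__Cyperaceae;g__Carex"),
            ],
        )
        lca = lca_collapse(a)
        assert lca.deepest_rank == "order"
        assert lca.get("order") == "Poales"

    def test_unassigned_stays_unassigned(self):
        assert lca_collapse(TaxonAssignment("OTU9", [])) is None

    @given(
        st.lists(
            st.lists(st.integers(0, 2), min_size=7, max_size=7), min_size=1, max_size=4
        )
    )
    def test_matches_longest_common_prefix_oracle(self, paths):
        # candidates as full root-to-species paths over a branching universe
        def to_lineage(path):
            names = []
            label = ""
            for rank, step in zip(RANKS, path):
                label += str(step)
                names.append((rank, f"{rank[:2]}_{label}"))
            return Lineage(tuple(names))

        a = TaxonAssignment("OTU", [to_lineage(p) for p in paths])
        # oracle: brute-force longest common prefix of the ranked paths
        depth = 0
        while depth < 7 and len({tuple(p[: depth + 1]) for p in paths}) == 1:
            depth += 1
        lca = lca_collapse(a)
        if depth == 0:
            assert lca is None
        else:
            assert len(lca.names) == depth
            assert lca.names == a.candidates[0].names[:depth]


class TestToRra:
    def test_hand_arithmetic(self):
        table = OtuTable(["S1"], ["OTU1", "OTU2", "OTU3"], np.array([[3, 1, 4]]))
        resolved = {"OTU1": "Rubus", "OTU2": "Rubus", "OTU3": "Smilax"}
        (rra,) = to_rra(table, resolved)
        assert dict(zip(rra.taxa, rra.proportions)) == {"Rubus": 0.5, "Smilax": 0.5}

    def test_single_taxon_sample(self):
        table = OtuTable(["S1"], ["OTU1"], np.array([[7]]))
        (rra,) = to_rra(table, {"OTU1": "Poa"})
        assert rra.proportions.tolist() == [1.0]

    def test_drop_unassigned_renormalizes(self):
        table = OtuTable(["S1"], ["OTU1", "OTU2"], np.array([[5, 5]]))
        resolved = {"OTU1": "Rubus", "OTU2": None}
        (rra,) = to_rra(table, resolved, drop_unassigned=True)
        assert dict(zip(rra.taxa, rra.proportions)) == {"Rubus": 1.0}
        (kept,) = to_rra(table, resolved, drop_unassigned=False)
        assert dict(zip(kept.taxa, kept.proportions)) == {"Rubus": 0.5, "unassigned": 0.5}

    def test_zero_retained_reads_is_error(self):
        table = OtuTable(["S1", "S2"], ["OTU1", "OTU2"], np.array([[5, 0], [0, 3]]))
        with pytest.raises(ValidationError, match="S2"):
            to_rra(table, {"OTU1": "Rubus", "OTU2": None})

    @given(
        st.lists(st.integers(0, 30), min_size=3, max_size=8).filter(lambda c: sum(c) > 0),
        st.lists(st.integers(0, 2), min_size=3, max_size=8),
    )
    def test_proportions_conserve_unit_sum(self, counts, labels):
        n = min(len(counts), len(labels))
        counts = counts[:n]
        if sum(counts) == 0:
            counts[0] = 1
        table = OtuTable(["S1"], [f"O{i}" for i in range(n)], np.array([counts]))
        resolved = {f"O{i}": f"T{labels[i]}" for i in range(n)}
        (rra,) = to_rra(table, resolved)
        assert abs(rra.proportions.sum() - 1.0) < 1e-9

    def test_rank_monotonicity(self, tiny_dataset):
        # aggregating at a higher rank never yields more categories
        n_taxa = {}
        for rank in ("species", "genus", "family", "order"):
            resolved = resolve_taxa(tiny_dataset.taxonomy, rank)
            rras = to_rra(tiny_dataset.table, resolved)
            n_taxa[rank] = max(int((r.proportions > 0).sum()) for r in rras)
        assert n_taxa["order"] <= n_taxa["family"] <= n_taxa["genus"] <= n_taxa["species"]


class TestPooling:
    meta = [
        SampleRecord("S1", Species.SIKA_DEER, Season.WINTER),
        SampleRecord("S2", Species.SIKA_DEER, Season.WINTER),
    ]

    def test_identical_samples_idempotent(self):
        table = OtuTable(["S1", "S2"], ["O1", "O2"], np.array([[3, 1], [3, 1]]))
        resolved = {"O1": "A", "O2": "B"}
        rras = to_rra(table, resolved)
        prof = pool_group_profile(
            rras, self.meta, Species.SIKA_DEER, Season.WINTER, "genus"
        )
        np.testing.assert_allclose(prof.proportions, [0.75, 0.25])

    def test_mean_rra_averages_disjoint_singletons(self):
        table = OtuTable(["S1", "S2"], ["O1", "O2"], np.array([[9, 0], [0, 10]]))
        resolved = {"O1": "A", "O2": "B"}
        rras = to_rra(table, resolved)
        prof = pool_group_profile(rras, self.meta, Species.SIKA_DEER, Season.WINTER, "genus")
        assert dict(zip(prof.taxa, prof.proportions)) == {"A": 0.5, "B": 0.5}

    def test_pooled_reads_weights_by_depth(self):
        table = OtuTable(["S1", "S2"], ["O1", "O2"], np.array([[9, 1], [0, 10]]))
        resolved = {"O1": "A", "O2": "B"}
        rras = to_rra(table, resolved)
        prof = pool_group_profile(
            rras, self.meta, Species.SIKA_DEER, Season.WINTER, "genus",
            method="pooled_reads", table=table, resolved=resolved,
        )
        assert dict(zip(prof.taxa, prof.proportions)) == {"A": 0.45, "B": 0.55}

    def test_mean_rra_order_invariant(self):
        table = OtuTable(["S1", "S2"], ["O1", "O2"], np.array([[9, 1], [2, 10]]))
        resolved = {"O1": "A", "O2": "B"}
        fwd = pool_group_profile(
            to_rra(table, resolved), self.meta, Species.SIKA_DEER, Season.WINTER, "genus"
        )
        rev_table = OtuTable(["S2", "S1"], ["O1", "O2"], np.array([[2, 10], [9, 1]]))
        rev = pool_group_profile(
            to_rra(rev_table, resolved), self.meta[::-1], Species.SIKA_DEER,
            Season.WINTER, "genus",
        )
        np.testing.assert_allclose(fwd.proportions, rev.proportions)

    def test_empty_group_is_error(self):
        table = OtuTable(["S1"], ["O1"], np.array([[3]]))
        rras = to_rra(table, {"O1": "A"})
        with pytest.raises(ValidationError, match="no samples"):
            pool_group_profile(rras, self.meta, Species.CHINESE_HARE, Season.FALL, "genus")


class TestDerivedTables:
    def test_top_n_all_fit_no_remainder(self):
        df = top_n_taxa(_profile(["A", "B", "C"], [0.5, 0.3, 0.2]), 10)
        assert list(df.taxon) == ["A", "B", "C"]
        assert "Others" not in set(df.taxon)

    def test_top_n_remainder_preserves_sum(self):
        df = top_n_taxa(_profile(["A", "B", "C"], [0.5, 0.3, 0.2]), 2)
        assert list(df.taxon) == ["A", "B", "Others"]
        assert df.proportion.sum() == pytest.approx(1.0)
        assert df.proportion.iloc[-1] == pytest.approx(0.2)

    def test_top_n_tie_breaks_alphabetical(self):
        df = top_n_taxa(_profile(["C", "B", "A"], [0.2, 0.4, 0.4]), 1)
        assert df.taxon.iloc[0] == "A"

    def test_growth_forms_sum_to_one_with_unknown(self):
        gmap = GrowthFormMap({"Rubus": GrowthForm.SHRUB, "Poa": GrowthForm.HERB})
        prof = _profile(["Rubus", "Poa", "Mystery"], [0.6, 0.3, 0.1])
        pct = growth_form_percentages(prof, gmap)
        assert pct == pytest.approx(
            {"herb": 0.3, "shrub": 0.6, "arbor": 0.0, "unknown": 0.1}
        )
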