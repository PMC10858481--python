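import numpy as np
import pandas as pd
import pytest

from mimelat.crossdata import (canonical_formula, core_microbiome,
                               harmonize_metabolites, harmonize_pair,
                               pair_consistency, parse_formula)
from mimelat.simulate import (GeneratorConfig, formula_map_for,
                              generate_multidataset, generate_paired)
from mimelat.tables import AbundanceTable, MetaboliteTable, PairedDataset
from mimelat.taxonomy import parse_taxonomy


# -- chemical formulas ------------------------------------------------------

@pytest.mark.parametrize("formula,counts", [
    ("C2H4O2", {"C": 2, "H": 4, "O": 2}),
    ("CH3COOH", {"C": 2, "H": 4, "O": 2}),
    ("Ca(OH)2", {"Ca": 1, "O": 2, "H": 2}),
    ("Fe2(SO4)3", {"Fe": 2, "S": 3, "O": 12}),
    ("NaCl", {"Na": 1, "Cl": 1}),
])
def test_formula_element_counts(formula, counts):
    assert parse_formula(formula) == counts


def test_condensed_and_molecular_forms_canonicalize_identically():
    assert canonical_formula("CH3COOH") == canonical_formula("C2H4O2")


def test_hill_order_carbon_first_then_hydrogen_then_alphabetical():
    assert canonical_formula("O2NH5C3") == "C3H5NO2"
    assert canonical_formula("ClNa") == "ClNa"  # no carbon: alphabetical


@pytest.mark.parametrize("bad", ["", "C2(H4", "c2h4"])
def test_malformed_formulas_rejected(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


# -- metabolite harmonization -----------------------------------------------

def test_exact_formula_match():
    fmap = pd.DataFrame({"name": ["acetic acid", "acetate"],
                         "formula": ["C2H4O2", "C2H4O2"]})
    matches, un_a, un_b = harmonize_metabolites(["acetic acid"], ["acetate"], fmap)
    assert len(matches) == 1
    assert matches.iloc[0]["formula"] == "C2H4O2"
    assert un_a == [] and un_b == []


def test_condensed_formula_matches_molecular_counterpart():
    fmap = {"a_met": "CH3COOH", "b_met": "C2H4O2"}
    matches, *_ = harmonize_metabolites(["a_met"], ["b_met"], fmap)
    assert len(matches) == 1


def test_unmapped_metabolite_reported_never_dropped_silently():
    fmap = {"known": "C6H12O6"}
    matches, un_a, un_b = harmonize_metabolites(["known", "mystery"], ["known"], fmap)
    assert "mystery" in un_a
    assert len(matches) == 1


def test_conflicting_formula_mapping_is_an_error():
    fmap = pd.DataFrame({"name": ["met", "met"],
                         "formula": ["C6H12O6", "C5H10O5"]})
    with pytest.raises(ValueError, match="two formulas"):
        harmonize_metabolites(["met"], ["met"], fmap)


# -- pair harmonization -----------------------------------------------------

@pytest.fixture(scope="module")
def two_cohorts():
    cfg = GeneratorConfig(n_samples=80, n_taxa=40, n_metabolites=20,
                          latent_dim_true=5, seed=11)
    sets = generate_multidataset(cfg, 2, share_relations=True,
                                 feature_overlap=0.5)
    dss = [d for d, _ in sets]
    return dss, formula_map_for(dss)


def test_half_overlap_on_forty_taxa_gives_twenty_shared(two_cohorts):
    dss, fmap = two_cohorts
    pair = harmonize_pair(dss[0], dss[1], fmap)
    assert len(pair.shared_taxa) == 20
    assert len(pair.shared_formulas) == 10


def test_harmonization_is_symmetric(two_cohorts):
    dss, fmap = two_cohorts
    ab = harmonize_pair(dss[0], dss[1], fmap)
    ba = harmonize_pair(dss[1], dss[0], fmap)
    assert ab.shared_taxa == ba.shared_taxa
    assert ab.shared_formulas == ba.shared_formulas


def test_harmonized_feature_ids_identical_and_ordered(two_cohorts):
    dss, fmap = two_cohorts
    pair = harmonize_pair(dss[0], dss[1], fmap)
    assert list(pair.dataset_a.microbiome.df.columns) == \
        list(pair.dataset_b.microbiome.df.columns)
    assert list(pair.dataset_a.metabolites.df.columns) == \
        list(pair.dataset_b.metabolites.df.columns)


def test_dropped_features_carry_provenance(two_cohorts):
    dss, fmap = two_cohorts
    pair = harmonize_pair(dss[0], dss[1], fmap)
    assert len(pair.dropped["taxa_a"]) == 20
    # the 10 metabolites outside the shared formula set are listed, not lost
    assert len(pair.dropped["metabolites_a"]) == 10


# -- core microbiome --------------------------------------------------------

def _cohort_with_orders(order_names, presence, n=30, name="c", seed=0):
    """Cohort whose taxon presence pattern is planted per order."""
    rng = np.random.default_rng(seed)
    cols = {}
    lineages = {}
    for order, frac in zip(order_names, presence):
        label = f"k__B;p__P;c__C;o__{order}"
        col = np.zeros(n)
        k = int(round(frac * n))
        col[:k] = rng.uniform(0.1, 1.0, size=k)
        cols[label] = col
        lineages[label] = parse_taxonomy(label)
    mi = AbundanceTable(pd.DataFrame(cols, index=[f"{name}{i}" for i in range(n)]),
                        lineages=lineages, state="raw")
    me = MetaboliteTable(pd.DataFrame({"m": np.ones(n)},
                                      index=mi.df.index), state="raw")
    return PairedDataset(mi, me, None, name=name)


def test_ubiquitous_taxon_aggregates_to_cohort_count():
    cohorts = [_cohort_with_orders(["X"], [1.0], name=f"c{i}", seed=i)
               for i in range(10)]
    core = core_microbiome(cohorts, min_aggregate_score=9.5)
    label = core.aggregate.index[0]
    assert core.aggregate[label] == pytest.approx(10.0)


def test_absent_taxon_scores_zero_and_is_excluded():
    cohorts = [_cohort_with_orders(["X", "Y"], [1.0, 0.0], name=f"c{i}", seed=i)
               for i in range(3)]
    core = core_microbiome(cohorts, min_aggregate_score=1.0)
    y_label = "k__B;p__P;c__C;o__Y"
    assert core.aggregate[y_label] == 0.0
    assert y_label not in core.core_taxa


def test_planted_common_orders_recovered():
    common = ["A", "B", "C", "D", "E"]
    cohorts = []
    for i in range(3):
        orders = common + [f"uniq{i}_{j}" for j in range(4)]
        presence = [1.0] * 5 + [0.4] * 4
        cohorts.append(_cohort_with_orders(orders, presence, name=f"c{i}", seed=i))
    core = core_microbiome(cohorts, min_aggregate_score=2.9)
    assert len(core.core_taxa) == 5


def test_core_aggregate_monotone_when_adding_cohort():
    cohorts = [_cohort_with_orders(["A", "B"], [0.8, 0.3], name=f"c{i}", seed=i)
               for i in range(3)]
    before = core_microbiome(cohorts[:2], min_aggregate_score=0.0).aggregate
    after = core_microbiome(cohorts, min_aggregate_score=0.0).aggregate
    for taxon in before.index:
        assert after[taxon] >= before[taxon] - 1e-12


# -- pair consistency -------------------------------------------------------

def test_planted_common_association_gives_positive_means():
    cfg = GeneratorConfig(n_samples=120, n_taxa=20, n_metabolites=10,
                          latent_dim_true=3, noise_sd_mic=0.2,
                          noise_sd_met=0.2, seed=5)
    sets = generate_multidataset(cfg, 3, share_relations=True,
                                 feature_overlap=1.0)
    mat = pair_consistency([d for d, _ in sets], p_threshold=0.05)
    strong = mat.pair_means[mat.pair_means.abs() > 0.3]
    assert (strong > 0).sum() > 0
    assert mat.all_scc.notna().all().all()


def test_independent_relations_center_pair_means_near_zero():
    cfg = GeneratorConfig(n_samples=120, n_taxa=20, n_metabolites=10,
                          latent_dim_true=3, noise_sd_mic=0.2,
                          noise_sd_met=0.2, seed=6)
    sets = generate_multidataset(cfg, 4, share_relations=False,
                                 feature_overlap=1.0)
    mat = pair_consistency([d for d, _ in sets], p_threshold=0.05)
    assert abs(mat.pair_means.mean()) < 0.1


def test_threshold_one_leaves_no_missing_entries():
    cfg = GeneratorConfig(n_samples=60, n_taxa=10, n_metabolites=5,
                          latent_dim_true=3, seed=7)
    sets = generate_multidataset(cfg, 2, share_relations=True,
                                 feature_overlap=1.0)
    mat = pair_consistency([d for d, _ in sets], p_threshold=1.0)
    assert not mat.matrix.isna().any().any()


def test_fewer_than_two_datasets_rejected():
    cfg = GeneratorConfig(n_samples=40, n_taxa=8, n_metabolites=4,
                          latent_dim_true=2, seed=8)
    ds, _ = generate_paired(cfg)
    with pytest.raises(ValueError, match="at least 2"):
        pair_consistency([ds])
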