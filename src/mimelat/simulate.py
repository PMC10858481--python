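"""Synthetic paired microbiome-metabolome cohorts with known ground truth.

Four generative regimes mirror the four conceptual models of the
microbiome-metabolome relation:

``linear``
    each metabolite is a non-negative linear combination of microbial
    relative abundances (production-network view);
``dominant``
    each metabolite is driven by a single producer taxon, which is drawn
    from the rare tercile with probability ``dominant_rarity_bias``;
``multiview``
    the host condition shifts microbiome and metabolome through disjoint
    channels with no shared latent layer (the two views are conditionally
    independent given the condition);
``latent``
    a shared low-dimensional latent factor ``U`` drives the log-scale
    signals of both views — microbiome log-signal ``U B'`` is exponentiated
    and renormalized into compositions, metabolite log-signal ``U C'`` is
    exponentiated into concentrations, and the condition label shifts the
    first half of the latent coordinates.

Every run stores the exact latent factors and loadings in a
:class:`SyntheticTruth`, sufficient to recompute the noiseless signals,
so the other modules can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import AbundanceTable, MetaboliteTable, PairedDataset
from .taxonomy import parse_taxonomy

REGIMES = ("linear", "dominant", "multiview", "latent")


@dataclass
class GeneratorConfig:
    """Study conditions of one synthetic cohort."""

    n_samples: int = 250
    n_taxa: int = 100
    n_metabolites: int = 50
    latent_dim_true: int = 10
    regime: str = "latent"
    noise_sd_mic: float = 0.05
    noise_sd_met: float = 0.05
    condition_effect: float = 1.0
    signal_scale: float = 1.0  # latent regime: decades of dynamic range
    dominant_rarity_bias: float = 0.7
    count_depth: int | None = None  # multinomial counts layer, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.noise_sd_mic < 0 or self.noise_sd_met < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.latent_dim_true > min(self.n_taxa, self.n_metabolites):
            raise ValueError("latent_dim_true must be <= min(n_taxa, n_metabolites)")
        if not (0.0 <= self.dominant_rarity_bias <= 1.0):
            raise ValueError("dominant_rarity_bias must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort (the generator's oracle)."""

    U: np.ndarray | None
    B: np.ndarray | None
    C: np.ndarray | None
    labels: np.ndarray
    producers: np.ndarray | None = None
    producer_weights: np.ndarray | None = None
    W: np.ndarray | None = None
    taxon_base: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _taxon_names(idx: np.ndarray) -> list[str]:
    return [f"k__Bacteria;p__P{i % 7};c__C{i % 13};o__Order{i}" for i in idx]


def _tables(comp: np.ndarray, conc: np.ndarray, labels: np.ndarray,
            continuous: np.ndarray, taxa_idx: np.ndarray,
            met_idx: np.ndarray, name: str,
            met_prefix: str = "", mi_state: str = "relative") -> PairedDataset:
    n = comp.shape[0]
    samples = [f"{name}_s{i:04d}" for i in range(n)]
    taxa = _taxon_names(taxa_idx)
    lineages = {t: parse_taxonomy(t) for t in taxa}
    mets = [f"{met_prefix}met{j}" for j in met_idx]
    formulas = {m: metabolite_formula(j) for m, j in zip(mets, met_idx)}
    mi = AbundanceTable(pd.DataFrame(comp, index=samples, columns=taxa),
                        lineages=lineages, state=mi_state)
    me = MetaboliteTable(pd.DataFrame(conc, index=samples, columns=mets),
                         formulas=formulas, state="raw")
    meta = pd.DataFrame({
        "condition": labels.astype(int),
        "age": continuous,
        "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
    }, index=samples)
    return PairedDataset(mi, me, meta, name=name)


def metabolite_formula(j: int) -> str:
    """Deterministic synthetic chemical formula for global metabolite j."""
    return f"C{2 + j % 9}H{4 + (j * 3) % 17}N{j % 3}O{1 + j % 5}".replace("N0", "")


def _unit_rows(M: np.ndarray) -> np.ndarray:
    """Rows rescaled to unit norm: every feature carries the latent signal
    at the same scale (avoids degenerate near-zero-loading features)."""
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    return M / np.where(norms == 0, 1.0, norms)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def generate_paired(config: GeneratorConfig,
                    taxa_idx: np.ndarray | None = None,
                    met_idx: np.ndarray | None = None,
                    loadings: tuple | None = None,
                    name: str = "synth",
                    met_prefix: str = "",
                    ) -> tuple[PairedDataset, SyntheticTruth]:
    """Generate one paired cohort under ``config.regime``.

    ``taxa_idx``/``met_idx`` name features from a global pool (used by the
    multi-dataset generator to control feature overlap); ``loadings`` lets
    datasets share ``(B, C)`` or the linear/dominant relation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p, m, d = cfg.n_samples, cfg.n_taxa, cfg.n_metabolites, cfg.latent_dim_true
    if taxa_idx is None:
        taxa_idx = np.arange(p)
    if met_idx is None:
        met_idx = np.arange(m)
    labels = rng.integers(0, 2, size=n).astype(float)
    continuous = rng.normal(50.0, 10.0, size=n)

    if cfg.regime == "latent":
        U = rng.standard_normal((n, d))
        shift_dims = np.arange((d + 1) // 2)
        U[:, shift_dims] += cfg.condition_effect * (labels[:, None] - 0.5)
        if loadings is None:
            B = _unit_rows(rng.standard_normal((p, d)))
            C = _unit_rows(rng.standard_normal((m, d)))
        else:
            B, C = loadings
        s = cfg.signal_scale
        mic_log = s * (U @ B.T) + cfg.noise_sd_mic * rng.standard_normal((n, p))
        met_log = s * (U @ C.T) + cfg.noise_sd_met * rng.standard_normal((n, m))
        comp = _softmax_rows(mic_log)
        conc = np.exp(met_log)
        truth = SyntheticTruth(U=U, B=B, C=C, labels=labels,
                               extras={"shift_dims": shift_dims,
                                       "continuous": continuous})

    elif cfg.regime == "linear":
        comp = rng.dirichlet(np.full(p, 0.8), size=n)
        if loadings is None:
            W = np.abs(rng.standard_normal((p, m))) * (rng.random((p, m)) < 0.2)
            W *= p / 5.0  # keep signal of order one against mean abundance 1/p
        else:
            (W,) = loadings
        conc = comp @ W + cfg.noise_sd_met * np.abs(rng.standard_normal((n, m)))
        conc = np.maximum(conc, 0.0)
        truth = SyntheticTruth(U=None, B=None, C=None, labels=labels, W=W,
                               extras={"continuous": continuous})

    elif cfg.regime == "dominant":
        base = rng.normal(0.0, 2.0, size=p)  # heterogeneous taxon frequencies
        logits = base[None, :] + rng.normal(0.0, 1.0, size=(n, p))
        comp = _softmax_rows(logits)
        freq = comp.mean(axis=0)
        order = np.argsort(freq)
        rare = order[: p // 3]
        common = order[p // 3:]
        producers = np.where(
            rng.random(m) < cfg.dominant_rarity_bias,
            rng.choice(rare, size=m),
            rng.choice(common, size=m),
        )
        # each metabolite's mean concentration is O(1) regardless of how
        # abundant its producer is (concentration units are set by the
        # chemistry, not by the producer's share of the community)
        weights = rng.uniform(0.5, 2.0, size=m) / freq[producers]
        conc = comp[:, producers] * weights[None, :]
        conc = conc * np.exp(cfg.noise_sd_met * rng.standard_normal((n, m)))
        truth = SyntheticTruth(U=None, B=None, C=None, labels=labels,
                               producers=producers, producer_weights=weights,
                               extras={"freq": freq, "continuous": continuous})

    elif cfg.regime == "multiview":
        # condition acts on each view through its own disjoint channel
        mic_channel = rng.choice(p, size=max(p // 10, 1), replace=False)
        met_channel = rng.choice(m, size=max(m // 10, 1), replace=False)
        logits = rng.normal(0.0, 1.0, size=(n, p))
        logits[:, mic_channel] += cfg.condition_effect * (labels[:, None] - 0.5)
        logits += cfg.noise_sd_mic * rng.standard_normal((n, p))
        comp = _softmax_rows(logits)
        met_log = rng.normal(0.0, 1.0, size=(n, m))
        met_log[:, met_channel] += cfg.condition_effect * (labels[:, None] - 0.5)
        met_log += cfg.noise_sd_met * rng.standard_normal((n, m))
        conc = np.exp(met_log)
        truth = SyntheticTruth(U=None, B=None, C=None, labels=labels,
                               extras={"mic_channel": mic_channel,
                                       "met_channel": met_channel,
                                       "continuous": continuous})

    if cfg.count_depth is not None:
        # sequencing-like counts: the log10(x + 0.1) chain only behaves as a
        # true log on count-scale values (the pseudocount swamps relative
        # abundances), so count emission is what makes log-linear structure
        # visible to the log-scale models
        counts = np.vstack([rng.multinomial(cfg.count_depth, row)
                            for row in comp]).astype(float)
        dataset = _tables(counts, conc, labels, continuous, taxa_idx, met_idx,
                          name=name, met_prefix=met_prefix, mi_state="raw")
    else:
        dataset = _tables(comp, conc, labels, continuous, taxa_idx, met_idx,
                          name=name, met_prefix=met_prefix)
    return dataset, truth


def generate_multidataset(config: GeneratorConfig, n_datasets: int,
                          share_relations: bool,
                          feature_overlap: float = 1.0,
                          ) -> list[tuple[PairedDataset, SyntheticTruth]]:
    """Generate several cohorts with controlled relation sharing.

    ``share_relations=True`` reuses the microbiome and metabolite loadings
    ``(B, C)`` across cohorts (cross-cohort transfer should work);
    ``False`` keeps the microbiome loading ``B`` (so the compositions look
    alike) but draws an independent metabolite loading ``C`` per cohort
    (context-dependent relations; transfer should degrade).  Consecutive
    cohorts share ``round(feature_overlap * n)`` taxa and metabolites from
    a global feature pool, and metabolite column names are cohort-specific
    so that harmonization by chemical formula is exercised downstream.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    if not (0.0 <= feature_overlap <= 1.0):
        raise ValueError("feature_overlap must be in [0, 1]")
    cfg = config
    if cfg.regime != "latent":
        raise ValueError("multi-dataset generation uses the latent regime")
    rng = np.random.default_rng(cfg.seed)
    p, m, d = cfg.n_taxa, cfg.n_metabolites, cfg.latent_dim_true
    step_t = p - int(round(feature_overlap * p))
    step_m = m - int(round(feature_overlap * m))
    # loadings are drawn per GLOBAL feature so a taxon or metabolite shared
    # by two cohorts keeps the same relation to the latent factors
    B_pool = _unit_rows(rng.standard_normal(((n_datasets - 1) * step_t + p, d)))
    C_pool = _unit_rows(rng.standard_normal(((n_datasets - 1) * step_m + m, d)))
    out = []
    for k in range(n_datasets):
        taxa_idx = np.arange(k * step_t, k * step_t + p)
        met_idx = np.arange(k * step_m, k * step_m + m)
        if share_relations:
            loadings = (B_pool[taxa_idx], C_pool[met_idx])
        else:
            rng_k = np.random.default_rng(cfg.seed + 1000 + k)
            Ck = _unit_rows(rng_k.standard_normal((m, d)))
            loadings = (B_pool[taxa_idx], Ck)
        sub = replace(cfg, seed=cfg.seed + k)
        ds, truth = generate_paired(sub, taxa_idx=taxa_idx, met_idx=met_idx,
                                    loadings=loadings, name=f"ds{k}",
                                    met_prefix=f"ds{k}_")
        out.append((ds, truth))
    return out


def formula_map_for(datasets: list[PairedDataset]) -> pd.DataFrame:
    """Two-column (name, formula) table covering all metabolites seen."""
    rows = []
    for ds in datasets:
        forms = ds.metabolites.formulas or {}
        for name, formula in forms.items():
            rows.append((name, formula))
    return pd.DataFrame(rows, columns=["name", "formula"]).drop_duplicates()
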