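"""Seeded synthetic data with planted ground truth for every pipeline stage.

No per-sample data accompany the study design this pipeline targets, so
each stage is exercised on generated inputs that reproduce the statistical
structure the stage assumes:

* two bulk cohorts with partially overlapping gene universes, incompatible
  quantification units, and a planted set of genes constructed to sit in
  the tumor cohort's top mean-expression tier and the normal cohort's
  bottom half;
* a digital-count panel run (counts, housekeeping genes, per-sample lane
  scale factors, optional low-expressing outlier tumor sample);
* a pan-cancer matrix with controllable per-(type, gene) expression
  intervals.

Background expression is log-normal on the linear scale (heavy-tailed,
strictly positive, so ranks are well defined); digital counts are Poisson
draws around scaled log-normal means; lane factors are log-normal and hit
every gene of a sample, housekeeping included -- exactly the nuisance the
normalization stage must remove. All randomness flows from the config
seed; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

#: The six housekeeping genes of the reference nCounter code set.
DEFAULT_HOUSEKEEPING = ["CLTC", "GAPDH", "GUSB", "HPRT1", "PGK1", "TUBB"]

#: TCGA study abbreviations for the 33 tumor types of the pan-cancer set.
TCGA_TYPE_CODES = [
    "ACC", "BLCA", "BRCA", "CESC", "CHOL", "COAD", "DLBC", "ESCA", "GBM",
    "HNSC", "KICH", "KIRC", "KIRP", "LAML", "LGG", "LIHC", "LUAD", "LUSC",
    "MESO", "OV", "PAAD", "PCPG", "PRAD", "READ", "SARC", "SKCM", "STAD",
    "TGCT", "THCA", "THYM", "UCEC", "UCS", "UVM",
]


# ---------------------------------------------------------------------------
# discovery cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscoverySimConfig:
    """Two-cohort discovery simulation.

    Defaults mirror the reference study design: 266 tumor and 97 normal
    samples, 41 planted biomarkers, and a shared universe large enough
    that the planted set fits inside the top-5% tier. Planted genes are
    constructed with tumor means far above the background maximum and
    normal means far below the background median, so their empirical
    mean-expression ranks land in the required tiers for any seed.
    """

    n_genes_common: int = 2000
    n_genes_extra_a: int = 300
    n_genes_extra_b: int = 500
    n_tumor_samples: int = 266
    n_normal_samples: int = 97
    n_planted: int = 41
    planted_tumor_percentile: float = 5.0
    planted_normal_percentile: float = 50.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    sample_log_sd: float = 0.25  # per-cell multiplicative noise (log scale)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes_common", "n_genes_extra_a", "n_genes_extra_b",
            "n_tumor_samples", "n_normal_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted < 0:
            raise ValueError("n_planted must be non-negative")
        capacity = int(np.floor(self.n_genes_common * self.planted_tumor_percentile / 100))
        if self.n_planted > capacity:
            raise ValueError(
                f"n_planted={self.n_planted} exceeds the top-"
                f"{self.planted_tumor_percentile}% tier capacity {capacity} "
                f"of {self.n_genes_common} common genes"
            )


def _lognormal_values(
    rng: np.random.Generator, means: np.ndarray, n_samples: int, log_sd: float
) -> np.ndarray:
    """Per-cell values = gene mean x lognormal multiplicative noise."""
    noise = rng.lognormal(mean=0.0, sigma=log_sd, size=(means.size, n_samples))
    return means[:, None] * noise


def generate_discovery_cohorts(
    config: DiscoverySimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, set[str]]:
    """Tumor (TPM-like) and normal (RPKM-like) cohorts plus planted truth.

    The two matrices use deliberately mismatched identifier spellings for
    the shared genes -- the tumor cohort carries dot-version suffixes and
    the normal cohort lower-case ids -- so that downstream identifier
    harmonization is exercised, not bypassed. The returned truth set uses
    canonical (upper-case, version-free) ids.
    """
    rng = np.random.default_rng(config.seed)
    common = [f"GC{i:05d}" for i in range(config.n_genes_common)]
    extra_a = [f"GA{i:05d}" for i in range(config.n_genes_extra_a)]
    extra_b = [f"GB{i:05d}" for i in range(config.n_genes_extra_b)]

    planted_idx = rng.choice(config.n_genes_common, size=config.n_planted, replace=False)
    truth = {common[i] for i in planted_idx}

    # independent background gene means per cohort (different platforms)
    means_tumor = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd,
        size=config.n_genes_common + config.n_genes_extra_a,
    )
    means_normal = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd,
        size=config.n_genes_common + config.n_genes_extra_b,
    )

    if config.n_planted:
        # plant far outside the background range: tumor means 20-80x the
        # background maximum, normal means 20-100x below the background
        # 5th percentile -- multiplicative noise cannot bridge those gaps
        top = means_tumor.max() * rng.uniform(20, 80, size=config.n_planted)
        means_tumor[planted_idx] = top
        low_ref = np.quantile(means_normal, 0.05)
        means_normal[planted_idx] = low_ref / rng.uniform(20, 100, size=config.n_planted)

    tumor_values = _lognormal_values(
        rng, means_tumor, config.n_tumor_samples, config.sample_log_sd
    )
    normal_values = _lognormal_values(
        rng, means_normal, config.n_normal_samples, config.sample_log_sd
    )

    tumor_ids = [f"{g}.1" for g in common] + extra_a
    normal_ids = [g.lower() for g in common] + extra_b
    tumor = ExpressionMatrix(
        values=pd.DataFrame(
            tumor_values,
            index=tumor_ids,
            columns=[f"TCGA_{i:04d}" for i in range(config.n_tumor_samples)],
        ),
        unit_label="TPM-like",
        sample_labels={f"TCGA_{i:04d}": "tumor" for i in range(config.n_tumor_samples)},
    )
    normal = ExpressionMatrix(
        values=pd.DataFrame(
            normal_values,
            index=normal_ids,
            columns=[f"GTEX_{i:04d}" for i in range(config.n_normal_samples)],
        ),
        unit_label="RPKM-like",
        sample_labels={f"GTEX_{i:04d}": "normal" for i in range(config.n_normal_samples)},
    )
    return tumor, normal, truth


# ---------------------------------------------------------------------------
# digital-count panel run
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSimConfig:
    """Digital-count (nCounter-style) panel simulation.

    Defaults mirror the reference run: a 41-gene panel plus 6 housekeeping
    genes measured on 42 tumor and 3 normal FFPE samples. Housekeeping
    expectation is cohort-independent and modulated only by the per-sample
    lane scale factor; panel genes are elevated ``tumor_over_expression_fold``
    fold in tumor samples (default 20, within the qualitative 3-300x
    over-expression range). With ``include_outlier`` one tumor sample draws
    its panel genes from the normal-level distribution while keeping its
    tumor label.
    """

    panel_genes: tuple[str, ...] = tuple(f"PANEL{i:02d}" for i in range(1, 42))
    n_housekeeping: int = 6
    n_tumor: int = 42
    n_normal: int = 3
    tumor_over_expression_fold: float = 20.0
    include_outlier: bool = True
    lane_scale_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel_genes:
            raise ValueError("panel_genes must be non-empty")
        if len(set(self.panel_genes)) != len(self.panel_genes):
            raise ValueError("panel_genes contains duplicates")
        for name in ("n_housekeeping", "n_tumor", "n_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tumor_over_expression_fold <= 0:
            raise ValueError("tumor_over_expression_fold must be positive")
        if self.lane_scale_sd < 0:
            raise ValueError("lane_scale_sd must be non-negative")
        hk = self._hk_names()
        if set(hk) & set(self.panel_genes):
            raise ValueError(
                f"housekeeping ids overlap panel ids: {sorted(set(hk) & set(self.panel_genes))}"
            )

    def _hk_names(self) -> list[str]:
        if self.n_housekeeping <= len(DEFAULT_HOUSEKEEPING):
            return DEFAULT_HOUSEKEEPING[: self.n_housekeeping]
        extra = [
            f"HK{i:02d}"
            for i in range(1, self.n_housekeeping - len(DEFAULT_HOUSEKEEPING) + 1)
        ]
        return DEFAULT_HOUSEKEEPING + extra


@dataclass
class NanoStringRun:
    """Generated panel run: raw counts, housekeeping ids, cohort labels."""

    raw_counts: ExpressionMatrix  # unit_label == "raw-count", integer values
    hk_genes: list[str]
    labels: dict[str, str]
    outlier_sample: str | None = None


def generate_nanostring_run(config: PanelSimConfig) -> NanoStringRun:
    """Poisson digital counts with lane-scale nuisance and planted effect."""
    rng = np.random.default_rng(config.seed)
    hk_genes = config._hk_names()
    panel = list(config.panel_genes)
    genes = panel + hk_genes

    tumor_ids = [f"T{i:02d}" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"N{i:02d}" for i in range(1, config.n_normal + 1)]
    samples = tumor_ids + normal_ids
    labels = {s: ("tumor" if s in set(tumor_ids) else "normal") for s in samples}

    # expected counts: housekeeping high and stable, panel lognormal baseline
    hk_means = rng.lognormal(np.log(1500.0), 0.3, size=len(hk_genes))
    panel_base = rng.lognormal(np.log(60.0), 0.8, size=len(panel))

    outlier: str | None = None
    if config.include_outlier:
        outlier = tumor_ids[int(rng.integers(config.n_tumor))]

    lane = rng.lognormal(0.0, config.lane_scale_sd, size=len(samples))

    expected = np.empty((len(genes), len(samples)))
    for j, s in enumerate(samples):
        tumor_like = labels[s] == "tumor" and s != outlier
        fold = config.tumor_over_expression_fold if tumor_like else 1.0
        expected[: len(panel), j] = panel_base * fold * lane[j]
        expected[len(panel):, j] = hk_means * lane[j]

    counts = rng.poisson(expected)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64),
        unit_label="raw-count",
        sample_labels=labels,
    )
    return NanoStringRun(
        raw_counts=matrix, hk_genes=hk_genes, labels=labels, outlier_sample=outlier
    )


# ---------------------------------------------------------------------------
# pan-cancer matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanCancerSimConfig:
    """Multi-type matrix with controllable per-(type, gene) intervals.

    ``interval_spec`` maps (type, gene) to a target [lo, hi]; values for
    designated pairs are drawn uniformly inside their interval (hence the
    empirical range is contained in the target), all other values come
    from a shared log-normal background. Unnamed types are filled from the
    33 TCGA study abbreviations.
    """

    n_types: int = 33
    samples_per_type: int = 333
    interval_spec: tuple[tuple[tuple[str, str], tuple[float, float]], ...] = ()
    background_log_mean: float = 1.0
    background_log_sd: float = 1.0
    n_background_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types <= 0 or self.samples_per_type <= 0:
            raise ValueError("n_types and samples_per_type must be positive")
        for (type_name, gene), (lo, hi) in self.interval_spec:
            if lo > hi:
                raise ValueError(
                    f"interval for type {type_name!r}, gene {gene!r} has lo > hi: "
                    f"[{lo}, {hi}]"
                )

    @staticmethod
    def from_dict(
        spec: dict[tuple[str, str], tuple[float, float]], **kwargs
    ) -> "PanCancerSimConfig":
        """Build a config from a {(type, gene): (lo, hi)} mapping."""
        return PanCancerSimConfig(
            interval_spec=tuple(sorted(spec.items())), **kwargs
        )

    def spec_dict(self) -> dict[tuple[str, str], tuple[float, float]]:
        return dict(self.interval_spec)


def generate_pan_cancer(
    config: PanCancerSimConfig,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Pan-cancer matrix with designated values inside their target intervals."""
    rng = np.random.default_rng(config.seed)
    spec = config.spec_dict()

    named_types = []
    for (t, _g) in spec:
        if t not in named_types:
            named_types.append(t)
    if len(named_types) > config.n_types:
        raise ValueError(
            f"interval_spec names {len(named_types)} types but n_types={config.n_types}"
        )
    fill = [t for t in TCGA_TYPE_CODES if t not in named_types]
    i = 0
    types = list(named_types)
    while len(types) < config.n_types:
        if i < len(fill):
            types.append(fill[i])
        else:
            types.append(f"TYPE{len(types):02d}")
        i += 1

    spec_genes = []
    for (_t, g) in spec:
        if g not in spec_genes:
            spec_genes.append(g)
    genes = spec_genes + [f"BG{i:04d}" for i in range(config.n_background_genes)]
    if not genes:
        raise ValueError("no genes to simulate: give interval_spec or n_background_genes")

    samples, type_labels = [], {}
    for t in types:
        for k in range(config.samples_per_type):
            sid = f"{t}_{k:03d}"
            samples.append(sid)
            type_labels[sid] = t

    values = rng.lognormal(
        config.background_log_mean, config.background_log_sd,
        size=(len(genes), len(samples)),
    )
    frame = pd.DataFrame(values, index=genes, columns=samples)
    for (t, g), (lo, hi) in spec.items():
        cols = [s for s in samples if type_labels[s] == t]
        frame.loc[g, cols] = rng.uniform(lo, hi, size=len(cols))

    matrix = ExpressionMatrix(
        values=frame, unit_label="RPKM-like", sample_labels=dict(type_labels)
    )
    return matrix, type_labels
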