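"""Synthetic matched-pair cohorts of subjects and per-cell interneuron measurements.

Generates case/control cohorts with a hierarchical lognormal measurement model
(between-subject effect x within-subject cell noise), programmed multiplicative
group effects per measure, subtype enrichment panels, and mixed PV/non-PV
populations with labelled ground truth for classifier evaluation.

Measures are generated on a latent log scale through a Gaussian copula so that
configured cell-level Pearson correlations hold on the raw (linear) scale.
Grain counts are lognormal-mixed Poisson with the cytoplasmic area as offset,
i.e. an overdispersed count model whose expected density equals the programmed
group mean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "COVARIATES",
    "COOCCURRING_FACTORS",
    "CohortConfigError",
    "CohortConfig",
    "SubjectRecord",
    "CellRecord",
    "CohortDataset",
    "generate_cohort",
    "generate_interneuron_panel",
    "generate_mixed_population",
    "validate_records",
]

#: latent measures drawn from the copula, in fixed order
MEASURES = (
    "cytoplasmic_rbfox1",
    "nuclear_rbfox1",
    "pv_intensity",
    "pv_grain_density",
    "vamp1_grain_density",
)

#: measures whose dependent variable is an mRNA readout (RIN is a candidate
#: covariate only for these)
MRNA_MEASURES = frozenset({"pv_grain_density", "vamp1_grain_density"})

COVARIATES = ("age", "brain_pH", "pmi", "rin", "storage")

COOCCURRING_FACTORS = (
    "schizoaffective",
    "substance_use",
    "nicotine",
    "antidepressants",
    "benzodiazepines",
    "valproic_acid",
    "suicide",
)

# population moments used to draw subject covariates (mean, sd); the paired
# structure adds a small within-pair difference on top of a shared pair level
_COVARIATE_MOMENTS = {
    "age": (45.8, 11.9),
    "brain_pH": (6.6, 0.25),
    "pmi": (15.9, 5.9),
    "rin": (8.1, 0.5),
    "storage": (107.0, 31.0),
}


class CohortConfigError(ValueError):
    """Raised for invalid cohort-generator configuration."""


@dataclass
class SubjectRecord:
    subject_id: str
    pair_id: int
    diagnosis: str  # {"comparison", "schizophrenia"}
    sex: str  # {"M", "F"}
    age: float
    brain_pH: float
    pmi: float
    rin: float
    storage: float
    cooccurring: frozenset = frozenset()

    def validate(self) -> None:
        if self.diagnosis not in ("comparison", "schizophrenia"):
            raise ValueError(f"bad diagnosis {self.diagnosis!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"bad sex {self.sex!r}")
        if not (self.age > 0 and 6.0 <= self.brain_pH <= 7.2 and self.pmi > 0
                and 0 < self.rin <= 10 and self.storage > 0):
            raise ValueError(f"covariates out of range for {self.subject_id}")
        unknown = set(self.cooccurring) - set(COOCCURRING_FACTORS)
        if unknown:
            raise ValueError(f"unknown co-occurring factors {unknown}")


@dataclass
class CellRecord:
    cell_id: str
    subject_id: str
    subtype: str  # {"PVI", "CBI", "CRI", "nonPV", "unknown"}
    layer: str  # {"L2", "L4"}
    body_intensity: float
    nuclear_intensity: float
    cytoplasmic_intensity: float
    pv_intensity: float
    body_area: float
    nucleus_area: float
    cytoplasm_area: float
    pv_grain_count: int
    vamp1_grain_count: int

    def validate(self) -> None:
        if self.subtype not in ("PVI", "CBI", "CRI", "nonPV", "unknown"):
            raise ValueError(f"bad subtype {self.subtype!r}")
        if min(self.body_intensity, self.nuclear_intensity,
               self.cytoplasmic_intensity, self.pv_intensity) < 0:
            raise ValueError("negative intensity")
        if not (0 < self.nucleus_area < self.body_area):
            raise ValueError("nucleus_area must lie in (0, body_area)")
        if abs(self.cytoplasm_area - (self.body_area - self.nucleus_area)) > 1e-6 * self.body_area:
            raise ValueError("cytoplasm_area != body_area - nucleus_area")
        if self.pv_grain_count < 0 or self.vamp1_grain_count < 0:
            raise ValueError("negative grain count")


def _default_baselines() -> dict:
    # reference-class means: rbfox measures are CRI-level (a.u.), pv_intensity
    # is PVI-level (a.u.), pv grain density is PVI-level, vamp1 is nonPV-level
    # (grains / um^2)
    return {
        "cytoplasmic_rbfox1": 12.0,
        "nuclear_rbfox1": 60.0,
        "pv_intensity": 100.0,
        "pv_grain_density": 0.50,
        "vamp1_grain_density": 0.20,
    }


def _default_sz_effects() -> dict:
    return {
        "cytoplasmic_rbfox1": 0.71,
        "nuclear_rbfox1": 0.71,
        "pv_intensity": 0.63,
        "pv_grain_density": 0.86,
        "cytoplasmic_rbfox1_frozen": 0.86,
        "vamp1_grain_density": 0.80,
    }


def _default_enrichment() -> dict:
    return {
        "cytoplasmic_rbfox1": {"PVI": 9.6, "CBI": 5.0, "CRI": 1.0},
        "nuclear_rbfox1": {"PVI": 3.0, "CBI": 2.6, "CRI": 1.0},
        "pv_intensity": {"PVI": 1.0, "CBI": 0.05, "CRI": 0.05},
    }


def _default_correlations() -> dict:
    return {
        ("cytoplasmic_rbfox1", "nuclear_rbfox1"): 0.6,
        ("cytoplasmic_rbfox1", "vamp1_grain_density"): 0.5,
    }


def _default_prevalence() -> dict:
    return {
        "schizoaffective": 0.20,
        "substance_use": 0.35,
        "nicotine": 0.60,
        "antidepressants": 0.30,
        "benzodiazepines": 0.25,
        "valproic_acid": 0.10,
        "suicide": 0.30,
    }


@dataclass
class CohortConfig:
    """Full parameterization of the cohort generator.

    ``sz_effects`` are multiplicative factors applied to the schizophrenia
    member of each pair: the expected schizophrenia/comparison ratio of group
    means equals the factor exactly. ``assay`` selects which effect keys apply
    ("fixed" protein assay vs "frozen" in situ assay, where the cytoplasmic
    deficit uses the ``cytoplasmic_rbfox1_frozen`` key).
    """

    n_pairs: int = 20
    cells_per_subject: int = 42
    assay: str = "fixed"
    baseline_means: dict = field(default_factory=_default_baselines)
    sz_effects: dict = field(default_factory=_default_sz_effects)
    subtype_enrichment: dict = field(default_factory=_default_enrichment)
    pv_vs_nonpv_vamp1_fold: float = 2.0
    nonpv_pv_grain_fold: float = 0.1
    cell_level_correlations: dict = field(default_factory=_default_correlations)
    between_subject_cv: float = 0.15
    within_subject_cv: float = 0.40
    covariate_effects: dict = field(default_factory=dict)  # (measure, covar) -> log slope per SD
    cooccurring_prevalence: dict = field(default_factory=_default_prevalence)
    body_area_mean: float = 300.0
    body_area_cv: float = 0.20
    nucleus_fraction_mean: float = 0.55
    nucleus_fraction_sd: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise CohortConfigError("n_pairs must be >= 2")
        if self.cells_per_subject < 1:
            raise CohortConfigError("cells_per_subject must be >= 1")
        if self.assay not in ("fixed", "frozen"):
            raise CohortConfigError(f"unknown assay {self.assay!r}")
        for k, v in self.sz_effects.items():
            if v <= 0:
                raise CohortConfigError(f"sz_effects[{k}] must be > 0")
        for m, folds in self.subtype_enrichment.items():
            if m not in MEASURES:
                raise CohortConfigError(f"unknown measure {m!r} in subtype_enrichment")
            for st, f in folds.items():
                if st not in ("PVI", "CBI", "CRI"):
                    raise CohortConfigError(f"unknown subtype {st!r} in subtype_enrichment")
                if f <= 0:
                    raise CohortConfigError("enrichment folds must be > 0")
        for (a, b), r in self.cell_level_correlations.items():
            if a not in MEASURES or b not in MEASURES:
                raise CohortConfigError(f"unknown measure pair ({a}, {b})")
            if not -1 < r < 1:
                raise CohortConfigError("correlations must lie in (-1, 1)")
        if self.between_subject_cv <= 0 or self.within_subject_cv <= 0:
            raise CohortConfigError("noise CVs must be > 0")
        if self.pv_vs_nonpv_vamp1_fold <= 0 or self.nonpv_pv_grain_fold <= 0:
            raise CohortConfigError("fold parameters must be > 0")
        # building the copula also checks positive-definiteness
        self._latent_correlation()

    # -- latent-scale machinery -------------------------------------------

    def _sigmas(self) -> tuple[float, float]:
        sb = float(np.sqrt(np.log1p(self.between_subject_cv ** 2)))
        sw = float(np.sqrt(np.log1p(self.within_subject_cv ** 2)))
        return sb, sw

    def _latent_correlation(self) -> np.ndarray:
        """Latent (log-scale) correlation matrix hitting the configured raw-scale
        Pearson targets for joint-lognormal pairs."""
        sb, sw = self._sigmas()
        s2 = sb ** 2 + sw ** 2
        omega = np.eye(len(MEASURES))
        idx = {m: i for i, m in enumerate(MEASURES)}
        for (a, b), r in self.cell_level_correlations.items():
            arg = 1.0 + r * (np.expm1(s2))  # equal sigmas for all measures
            if arg <= 0:
                raise CohortConfigError(f"target correlation {r} unattainable")
            rho = np.log(arg) / s2
            omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = rho
        try:
            np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as exc:
            raise CohortConfigError("correlation matrix not positive-definite") from exc
        return omega

    def effect_for(self, measure: str, assay: str | None = None) -> float:
        """Schizophrenia multiplicative factor for a measure under an assay."""
        assay = assay or self.assay
        if assay == "frozen" and measure == "cytoplasmic_rbfox1":
            return self.sz_effects.get("cytoplasmic_rbfox1_frozen", 1.0)
        return self.sz_effects.get(measure, 1.0)


@dataclass
class CohortDataset:
    """Subjects + cells tables with the generating config and seed."""

    subjects: pd.DataFrame
    cells: pd.DataFrame
    config: CohortConfig
    seed: int

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(path / "subjects.csv", index=False)
        self.cells.to_csv(path / "cells.csv", index=False)
        meta = dataclasses.asdict(self.config)
        meta["cell_level_correlations"] = {
            "|".join(k): v for k, v in self.config.cell_level_correlations.items()
        }
        meta["covariate_effects"] = {
            "|".join(k): v for k, v in self.config.covariate_effects.items()
        }
        (path / "config.json").write_text(
            json.dumps({"seed": self.seed, "config": meta}, indent=2)
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "CohortDataset":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        cfg_dict = meta["config"]
        cfg_dict["cell_level_correlations"] = {
            tuple(k.split("|")): v
            for k, v in cfg_dict["cell_level_correlations"].items()
        }
        cfg_dict["covariate_effects"] = {
            tuple(k.split("|")): v for k, v in cfg_dict["covariate_effects"].items()
        }
        config = CohortConfig(**cfg_dict)
        subjects = pd.read_csv(path / "subjects.csv")
        cells = pd.read_csv(path / "cells.csv")
        return cls(subjects=subjects, cells=cells, config=config, seed=meta["seed"])


# -- subject generation ----------------------------------------------------


def _draw_subjects(config: CohortConfig, rng: np.random.Generator,
                   diagnoses: bool = True) -> pd.DataFrame:
    """Draw paired subject covariates. With ``diagnoses`` False all subjects
    are unaffected (used for the subtype panel)."""
    rows = []
    for pair in range(1, config.n_pairs + 1):
        sex = "M" if rng.random() < 0.75 else "F"
        base = {}
        deltas = {}
        for cov, (mu, sd) in _COVARIATE_MOMENTS.items():
            # shared pair level + within-pair difference
            base[cov] = rng.normal(mu, sd * 0.9)
            deltas[cov] = rng.normal(0.0, sd * 0.45)
        for member, diag in (("C", "comparison"), ("Z", "schizophrenia")):
            sign = 0.5 if member == "C" else -0.5
            row = {
                "subject_id": f"S{pair:03d}{member}",
                "pair_id": pair,
                "diagnosis": diag if diagnoses else "comparison",
                "sex": sex,
            }
            for cov in COVARIATES:
                row[cov] = base[cov] + sign * deltas[cov]
            # clip into valid ranges
            row["age"] = float(np.clip(row["age"], 18.0, 90.0))
            row["brain_pH"] = float(np.clip(row["brain_pH"], 6.0, 7.2))
            row["pmi"] = float(np.clip(row["pmi"], 2.0, 40.0))
            row["rin"] = float(np.clip(row["rin"], 5.0, 10.0))
            row["storage"] = float(np.clip(row["storage"], 12.0, 240.0))
            sz = diagnoses and diag == "schizophrenia"
            for factor in COOCCURRING_FACTORS:
                p = config.cooccurring_prevalence.get(factor, 0.0)
                row[factor] = bool(sz and rng.random() < p)
            rows.append(row)
    return pd.DataFrame(rows)


# -- cell generation -------------------------------------------------------


def _cell_means(config: CohortConfig, subtype: str) -> np.ndarray:
    """Linear-scale expected cell means per measure for one subtype."""
    base = config.baseline_means
    means = np.empty(len(MEASURES))
    for i, m in enumerate(MEASURES):
        v = base[m]
        folds = config.subtype_enrichment.get(m)
        if folds is not None:
            v *= folds.get(subtype if subtype in ("PVI", "CBI", "CRI") else "CRI", 1.0)
        means[i] = v
    i_pv = MEASURES.index("pv_grain_density")
    i_v1 = MEASURES.index("vamp1_grain_density")
    if subtype == "PVI":
        means[i_v1] = base["vamp1_grain_density"] * config.pv_vs_nonpv_vamp1_fold
    else:
        means[i_pv] = base["pv_grain_density"] * config.nonpv_pv_grain_fold
        if subtype in ("CBI", "CRI", "nonPV"):
            means[MEASURES.index("pv_intensity")] = (
                base["pv_intensity"]
                * config.subtype_enrichment.get("pv_intensity", {}).get("CBI", 0.05)
            )
    return means


def _sample_cells(config: CohortConfig, rng: np.random.Generator,
                  subject_id: str, subtype: str, n_cells: int,
                  mean_vector: np.ndarray, subject_effect: np.ndarray,
                  layer_choices: tuple[str, ...], start_index: int = 0,
                  covariate_shift: np.ndarray | None = None) -> list[dict]:
    """Sample ``n_cells`` CellRecords rows for one subject and subtype."""
    sb, sw = config._sigmas()
    omega = config._latent_correlation()
    s2 = sb ** 2 + sw ** 2
    mu = np.log(mean_vector) - 0.5 * s2
    if covariate_shift is not None:
        mu = mu + covariate_shift
    chol = np.linalg.cholesky(omega)
    z = rng.standard_normal((n_cells, len(MEASURES))) @ chol.T
    log_values = mu + subject_effect + sw * z
    values = np.exp(log_values)

    body_sigma = np.sqrt(np.log1p(config.body_area_cv ** 2))
    body_area = np.exp(
        np.log(config.body_area_mean) - 0.5 * body_sigma ** 2
        + body_sigma * rng.standard_normal(n_cells)
    )
    frac = np.clip(
        rng.normal(config.nucleus_fraction_mean, config.nucleus_fraction_sd, n_cells),
        0.25, 0.85,
    )
    nucleus_area = frac * body_area
    cytoplasm_area = body_area - nucleus_area

    cyto = values[:, MEASURES.index("cytoplasmic_rbfox1")]
    nuc = values[:, MEASURES.index("nuclear_rbfox1")]
    body = (nuc * nucleus_area + cyto * cytoplasm_area) / body_area

    pv_density = values[:, MEASURES.index("pv_grain_density")]
    v1_density = values[:, MEASURES.index("vamp1_grain_density")]
    pv_counts = rng.poisson(pv_density * cytoplasm_area)
    v1_counts = rng.poisson(v1_density * cytoplasm_area)

    layers = rng.choice(layer_choices, size=n_cells)
    rows = []
    for i in range(n_cells):
        rows.append({
            "cell_id": f"{subject_id}-{subtype}-{start_index + i:04d}",
            "subject_id": subject_id,
            "subtype": subtype,
            "layer": str(layers[i]),
            "body_intensity": float(body[i]),
            "nuclear_intensity": float(nuc[i]),
            "cytoplasmic_intensity": float(cyto[i]),
            "pv_intensity": float(values[i, MEASURES.index("pv_intensity")]),
            "body_area": float(body_area[i]),
            "nucleus_area": float(nucleus_area[i]),
            "cytoplasm_area": float(cytoplasm_area[i]),
            "pv_grain_count": int(pv_counts[i]),
            "vamp1_grain_count": int(v1_counts[i]),
        })
    return rows


def _covariate_shift(config: CohortConfig, subject_row: pd.Series) -> np.ndarray:
    """Log-scale mean shift from programmed covariate effects (zero by default)."""
    shift = np.zeros(len(MEASURES))
    if not config.covariate_effects:
        return shift
    for (measure, cov), beta in config.covariate_effects.items():
        mu, sd = _COVARIATE_MOMENTS[cov]
        z = (subject_row[cov] - mu) / sd
        shift[MEASURES.index(measure)] += beta * z
    return shift


def generate_cohort(config: CohortConfig, seed: int | None = None) -> CohortDataset:
    """Generate a full matched-pair cohort of PVI cell measurements.

    Each pair contributes one comparison and one schizophrenia subject sharing
    sex; every measure in ``config.sz_effects`` (resolved through the assay)
    is multiplied by its group factor for schizophrenia subjects, so the
    expected schizophrenia/comparison ratio of group means equals the factor.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    subjects = _draw_subjects(config, rng, diagnoses=True)

    sb, _ = config._sigmas()
    omega = config._latent_correlation()
    chol = np.linalg.cholesky(omega)

    layer_choices = ("L2", "L4") if config.assay == "fixed" else ("L4",)
    pvi_means = _cell_means(config, "PVI")
    effects = np.array([config.effect_for(m) for m in MEASURES])

    cell_rows: list[dict] = []
    for pair in range(1, config.n_pairs + 1):
        for diag in ("comparison", "schizophrenia"):
            row = subjects[(subjects.pair_id == pair)
                           & (subjects.diagnosis == diag)].iloc[0]
            subject_effect = sb * (chol @ rng.standard_normal(len(MEASURES)))
            means = pvi_means * (effects if diag == "schizophrenia" else 1.0)
            cell_rows.extend(_sample_cells(
                config, rng, row.subject_id, "PVI", config.cells_per_subject,
                means, subject_effect, layer_choices,
                covariate_shift=_covariate_shift(config, row),
            ))
    cells = pd.DataFrame(cell_rows)
    return CohortDataset(subjects=subjects, cells=cells, config=config, seed=seed)


def generate_interneuron_panel(config: CohortConfig, n_subjects: int = 3,
                               seed: int | None = None) -> CohortDataset:
    """Generate unaffected subjects each carrying PVI, CBI and CRI cells whose
    expected measure means obey the configured subtype enrichment folds."""
    config.validate()
    if n_subjects < 1:
        raise CohortConfigError("n_subjects must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    panel_cfg = dataclasses.replace(config, n_pairs=max(2, n_subjects))
    subjects = _draw_subjects(panel_cfg, rng, diagnoses=False)
    subjects = subjects[subjects.subject_id.str.endswith("C")].head(n_subjects)
    subjects = subjects.reset_index(drop=True)

    sb, _ = config._sigmas()
    chol = np.linalg.cholesky(config._latent_correlation())
    cell_rows: list[dict] = []
    for _, row in subjects.iterrows():
        for subtype in ("PVI", "CBI", "CRI"):
            subject_effect = sb * (chol @ rng.standard_normal(len(MEASURES)))
            cell_rows.extend(_sample_cells(
                config, rng, row.subject_id, subtype, config.cells_per_subject,
                _cell_means(config, subtype), subject_effect, ("L2", "L4"),
            ))
    cells = pd.DataFrame(cell_rows)
    return CohortDataset(subjects=subjects, cells=cells, config=config, seed=seed)


def generate_mixed_population(config: CohortConfig, n_cells: int,
                              pvi_fraction: float,
                              seed: int | None = None) -> pd.DataFrame:
    """Generate a mixed PVI / non-PV population with true labels retained.

    PV grain counts come from two well-separated count distributions and Vamp1
    grain density carries the configured PVI/non-PV fold; the ``subtype``
    column holds the ground-truth label for classifier evaluation.
    """
    config.validate()
    if not 0 < pvi_fraction < 1:
        raise CohortConfigError("pvi_fraction must lie in (0, 1)")
    if n_cells < 1:
        raise CohortConfigError("n_cells must be >= 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    labels = rng.random(n_cells) < pvi_fraction
    sb, _ = config._sigmas()
    chol = np.linalg.cholesky(config._latent_correlation())
    subject_effect = np.zeros(len(MEASURES))  # single pooled "subject"
    rows: list[dict] = []
    for subtype, mask in (("PVI", labels), ("nonPV", ~labels)):
        n = int(mask.sum())
        if n == 0:
            continue
        rows.extend(_sample_cells(
            config, rng, "MIX", subtype, n,
            _cell_means(config, subtype), subject_effect, ("L4",),
            start_index=len(rows),
        ))
    return pd.DataFrame(rows)


def validate_records(dataset: CohortDataset) -> None:
    """Check every emitted subject and cell row against its type invariants."""
    for _, row in dataset.subjects.iterrows():
        SubjectRecord(
            subject_id=row.subject_id, pair_id=int(row.pair_id),
            diagnosis=row.diagnosis, sex=row.sex, age=row.age,
            brain_pH=row.brain_pH, pmi=row.pmi, rin=row.rin,
            storage=row.storage,
            cooccurring=frozenset(
                f for f in COOCCURRING_FACTORS if f in row and bool(row[f])
            ),
        ).validate()
    for _, row in dataset.cells.iterrows():
        CellRecord(
            cell_id=row.cell_id, subject_id=row.subject_id,
            subtype=row.subtype, layer=row.layer,
            body_intensity=row.body_intensity,
            nuclear_intensity=row.nuclear_intensity,
            cytoplasmic_intensity=row.cytoplasmic_intensity,
            pv_intensity=row.pv_intensity, body_area=row.body_area,
            nucleus_area=row.nucleus_area, cytoplasm_area=row.cytoplasm_area,
            pv_grain_count=int(row.pv_grain_count),
            vamp1_grain_count=int(row.vamp1_grain_count),
        ).validate()
    # pair invariants
    for pair_id, grp in dataset.subjects.groupby("pair_id"):
        if len(grp) == 2:
            if grp.sex.nunique() != 1:
                raise ValueError(f"pair {pair_id} members differ in sex")
            if sorted(grp.diagnosis) != ["comparison", "schizophrenia"]:
                raise ValueError(f"pair {pair_id} lacks one case and one control")
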