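"""Trait-table handling, log-shape-ratio size correction, mass imputation, PCA.

Linear limb measurements (mm) are made dimensionally comparable across body
sizes by the log-shape ratio ``log10(trait / mass^(1/3))`` with body mass in
grams; species values are arithmetic specimen means taken before the
transform.  Fossil body masses are imputed from a log10-log10 allometric
regression of mass on the geometric mean of all linear measurements fitted
to extant flyers.  PCA is an eigendecomposition of the trait covariance
matrix with divisor n (the ``princomp`` convention); component signs are
arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FORELIMB_TRAITS",
    "HINDLIMB_TRAITS",
    "TraitTable",
    "ShapeRatioMatrix",
    "PCResult",
    "log_shape_ratios",
    "estimate_fossil_mass",
    "pca",
]

#: 14 forelimb measurement abbreviations (scapula, humerus, radius, ulna,
#: third manual digit)
FORELIMB_TRAITS = ("sh", "sl", "hl", "hdw", "hpw", "hsw", "rl", "ul", "uol",
                   "mcl", "mcw", "ppl", "ppw", "ipl")
#: 15 hindlimb measurement abbreviations (pelvis, femur, tibia, fibula,
#: third pedal digit)
HINDLIMB_TRAITS = ("pel", "il", "isl", "fl", "fdw", "fsw", "tl", "tpw", "tmw",
                   "fbl", "mtl", "mtw", "ppxl", "ppxw", "ipxl")


@dataclass
class TraitTable:
    """Specimen-level linear measurements (mm) with species identity.

    ``data`` holds one row per specimen: columns ``species``, optional
    ``specimen``, ``sex``, ``extinct``, plus one column per trait.  All
    measurements must be positive where present (missing = NaN).
    """

    data: pd.DataFrame
    traits: tuple

    def __post_init__(self):
        if "species" not in self.data.columns:
            raise ValueError("trait table needs a 'species' column")
        missing = [t for t in self.traits if t not in self.data.columns]
        if missing:
            raise ValueError(f"trait columns absent from table: {missing}")
        vals = self.data[list(self.traits)].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("non-positive measurement in trait table")

    @classmethod
    def read_csv(cls, path, traits=None, column_map=None) -> "TraitTable":
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns=column_map)
        if traits is None:
            reserved = {"species", "specimen", "sex", "mass_g", "extinct"}
            traits = tuple(c for c in df.columns if c not in reserved)
        return cls(df, tuple(traits))

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @property
    def species(self) -> list:
        return list(dict.fromkeys(self.data["species"]))

    def species_means(self) -> pd.DataFrame:
        """Arithmetic specimen mean per species and trait (mm)."""
        return self.data.groupby("species", sort=False)[list(self.traits)].mean()


@dataclass
class ShapeRatioMatrix:
    """Species x trait log-shape ratios with the mass vector used."""

    ratios: pd.DataFrame  # species x trait, log10(mm / g^(1/3))
    masses: pd.Series  # g
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.ratios.to_numpy())):
            raise ValueError("non-finite log-shape ratio")

    @property
    def species(self) -> list:
        return list(self.ratios.index)


def log_shape_ratios(table: TraitTable, masses) -> ShapeRatioMatrix:
    """Size-correct a trait table: ``log10(mean trait / mass^(1/3))``.

    ``masses`` maps species to body mass in grams (species-level literature
    masses, not specimen masses).
    """
    masses = pd.Series(masses, dtype=float)
    means = table.species_means()
    missing = [sp for sp in means.index if sp not in masses.index]
    if missing:
        raise KeyError(f"no body mass for species: {missing}")
    m = masses.loc[means.index]
    if np.any(m <= 0):
        bad = list(m.index[m <= 0])
        raise ValueError(f"non-positive mass for species: {bad}")
    if means.isna().any().any():
        bad = means.index[means.isna().any(axis=1)].tolist()
        raise ValueError(f"species with missing trait means: {bad}")
    ratios = np.log10(means.div(np.cbrt(m), axis=0))
    return ShapeRatioMatrix(ratios, m, meta={"transform": "log10(mm * g^(-1/3))"})


def estimate_fossil_mass(extant: TraitTable, extant_masses,
                         fossil_measurements: pd.DataFrame) -> pd.Series:
    """Impute fossil body masses from extant-flyer allometry.

    Fits ``log10(mass) ~ log10(geometric mean of all measurements)`` by
    ordinary least squares on the extant table (the paper's extant bats),
    then back-transforms predictions for each fossil row.  Returns grams.
    """
    masses = pd.Series(extant_masses, dtype=float)
    means = extant.species_means()
    if means.isna().any().any() or len(means) < 3:
        raise ValueError("need >= 3 extant species with complete measurements")
    gm = np.log10(np.exp(np.log(means).mean(axis=1)))
    y = np.log10(masses.loc[means.index])
    slope, intercept = np.polyfit(gm.to_numpy(), y.to_numpy(), 1)

    missing = fossil_measurements.columns[fossil_measurements.isna().any()]
    if fossil_measurements.isna().any().any():
        raise ValueError(f"fossil measurements missing in columns: {list(missing)}")
    fgm = np.log10(np.exp(np.log(fossil_measurements).mean(axis=1)))
    pred = 10.0 ** (intercept + slope * fgm)
    pred.attrs["regression"] = {"slope": float(slope), "intercept": float(intercept),
                                "scale": "log10-log10"}
    return pred


@dataclass
class PCResult:
    """Principal components of the trait covariance matrix.

    Loadings columns are orthonormal eigenvectors ordered by decreasing
    variance; scores are centered projections; ``variance_fractions`` sum
    to 1 over all components.
    """

    loadings: pd.DataFrame  # trait x component
    scores: pd.DataFrame  # species x component
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(ratios: ShapeRatioMatrix | pd.DataFrame) -> PCResult:
    """Covariance-matrix PCA of log-shape ratios (divisor n).

    Returns all components; trailing zero-variance components of
    rank-deficient input are retained with zero variance fraction.
    """
    X = ratios.ratios if isinstance(ratios, ShapeRatioMatrix) else ratios
    if X.isna().any().any():
        raise ValueError("missing entries; PCA input must be complete")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 species and >= 2 traits")
    M = X.to_numpy(dtype=float)
    centered = M - M.mean(axis=0)
    cov = centered.T @ centered / len(M)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=X.columns, columns=comps)
    scores = pd.DataFrame(centered @ evecs, index=X.index, columns=comps)
    total = evals.sum()
    fracs = evals / total if total > 0 else np.zeros_like(evals)
    return PCResult(loadings, scores, fracs)
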