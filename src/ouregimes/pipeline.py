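"""Configuration-driven orchestration of the full comparative analysis.

One entry point per study design: :func:`run_multivariate` (PC scores,
six-model comparison in the shape of the paper-style mAICcW table),
:func:`run_univariate` (per-trait six-model comparison with bootstrap CIs
and an optima-ordering summary), and :func:`run_with_fossils` (grafted
non-ultrametric tree, imputed fossil masses).  Each run emits a manifest
recording config, seeds, stage timings, and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evomodels import ModelSpec, akaike_weights, fit_model
from .morphometrics import (ShapeRatioMatrix, TraitTable, estimate_fossil_mass,
                            log_shape_ratios, pca)
from .phylo import Phylogeny, graft_fossil_clade, prune_to_tips, read_tree
from .regime_mapping import (CATEGORIES, SCHEMES, fit_mk_er, paint_scheme,
                             sample_simmap)
from .uncertainty import bootstrap_optima

__all__ = [
    "RunConfig",
    "RunManifest",
    "DEFAULT_FAMILIES",
    "run_multivariate",
    "run_univariate",
    "run_with_fossils",
    "format_optima_ordering",
]

DEFAULT_FAMILIES = ("BM", "OU1", "OUM_loc4", "OUM_loc3a", "OUM_loc3b",
                    "OUM_loc3c")

#: display abbreviations used in optima-ordering strings
_SHORT = {"ground": "ground", "arboreal": "arb", "glider": "glide",
          "flyer": "bat"}


@dataclass
class FossilSpec:
    """Fossils to graft: names, measurements, host clade, and ages (Myr)."""

    names: list
    measurements: pd.DataFrame  # fossil x trait, mm
    host_clade: list  # extant tip labels whose stem receives the polytomy
    stem_age: float = 69.8
    tip_ages: object = 50.0  # scalar or per-fossil mapping; Eocene default
    category: str = "flyer"


@dataclass
class RunConfig:
    """Inputs and replication settings for one analysis run.

    Inputs may be file paths (``tree_files``, ``trait_csv``, ``mass_csv``,
    ``regime_csv``) or in-memory objects (``trees``, ``trait_table``,
    ``masses``, ``categories``); in-memory values win.
    """

    tree_files: list = None
    trees: list = None
    trait_csv: str = None
    trait_table: TraitTable = None
    traits: tuple = None
    mass_csv: str = None
    masses: object = None
    regime_csv: str = None
    categories: dict = None
    limb: str = "forelimb"
    fossils: FossilSpec = None
    n_pcs: int = 3
    families: tuple = DEFAULT_FAMILIES
    n_trees: int = 10
    maps_per_tree: int = 1
    fossil_maps: int = 50
    bootstrap_maps: int = 10
    bootstrap_reps: int = 10
    seed: int = 0
    outdir: str = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def echo(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (str, int, float, bool, tuple, list)) or v is None:
                out[f.name] = list(v) if isinstance(v, tuple) else v
            else:
                out[f.name] = f"<{type(v).__name__}>"
        return out


@dataclass
class RunManifest:
    """Provenance record: config echo, seeds, timings, output checksums."""

    config: dict
    version: str = __version__
    seed: int = 0
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    warnings: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def add_output(self, path):
        with open(path, "rb") as fh:
            self.outputs[str(path)] = hashlib.sha256(fh.read()).hexdigest()

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ------------------------------------------------------------- input loading

def _resolve_inputs(config: RunConfig):
    if config.trees is not None:
        trees = list(config.trees)
    elif config.tree_files:
        trees = [read_tree(p) for p in config.tree_files]
    else:
        raise ValueError("no trees supplied")
    if config.trait_table is not None:
        table = config.trait_table
    elif config.trait_csv:
        table = TraitTable.read_csv(config.trait_csv, traits=config.traits)
    else:
        raise ValueError("no trait table supplied")
    if config.masses is not None:
        masses = pd.Series(config.masses, dtype=float)
    elif config.mass_csv:
        df = pd.read_csv(config.mass_csv)
        masses = df.set_index("species")["mass_g"].astype(float)
    else:
        raise ValueError("no body masses supplied")
    if config.categories is not None:
        categories = dict(config.categories)
    elif config.regime_csv:
        df = pd.read_csv(config.regime_csv)
        categories = dict(zip(df["species"], df["category"]))
    else:
        raise ValueError("no locomotor categories supplied")
    return trees, table, masses, categories


def _family_spec(name: str) -> ModelSpec:
    if name == "BM":
        return ModelSpec("BM", root_mode="free")
    if name == "OU1":
        return ModelSpec("OU1")
    if name.startswith("OUM_"):
        scheme = name.split("_", 1)[1]
        if scheme not in SCHEMES:
            raise ValueError(f"unknown painting scheme in family {name!r}")
        return ModelSpec("OUM", scheme=scheme)
    raise ValueError(f"unknown model family {name!r}")


def _restrict_tree(tree: Phylogeny, species) -> Phylogeny:
    keep = set(species)
    labels = set(tree.tip_labels)
    if not keep <= labels:
        raise ValueError(f"tree lacks species: {sorted(keep - labels)[:5]}")
    if keep == labels:
        return tree
    return prune_to_tips(tree, keep)


# ------------------------------------------------------------- core fitting

def _scheme_maps(tree, categories, schemes, maps_per_tree, rng):
    """Fit Mk and sample simmaps per painting scheme on one tree."""
    out = {}
    for scheme in schemes:
        painted = paint_scheme(categories, scheme)
        tip_states = {lab: painted[lab] for lab in tree.tip_labels}
        mk = fit_mk_er(tree, tip_states)
        out[scheme] = (mk, sample_simmap(tree, tip_states, mk, maps_per_tree,
                                         seed=int(rng.integers(2 ** 31))))
    return out


def _fit_replicates(trees, traits, categories, families, maps_per_tree, rng):
    """Fit every family on every (tree, map index) replicate.

    Each OUM family uses simmaps of its own painting; BM/OU1 ignore the map.
    Returns (model names, AICc matrix, per-replicate fit lists, mk rates).
    """
    specs = [_family_spec(f) for f in families]
    schemes = [s.scheme for s in specs if s.family == "OUM"]
    rows, fits_all, q_hats = [], [], []
    for tree in trees:
        smaps = _scheme_maps(tree, categories, schemes, maps_per_tree, rng)
        q_hats.append({s: smaps[s][0].q for s in schemes})
        for im in range(maps_per_tree):
            fits = []
            for spec in specs:
                if spec.family == "OUM":
                    rmap = smaps[spec.scheme][1][im]
                else:
                    rmap = smaps[schemes[0]][1][im] if schemes else None
                    if rmap is None:
                        from .regime_mapping import RegimeMap
                        rmap = RegimeMap.constant(tree, "__single__")
                fits.append(fit_model(tree, [rmap], traits, spec)[0])
            rows.append([f.aicc for f in fits])
            fits_all.append(fits)
    return list(families), np.array(rows), fits_all, q_hats


@dataclass
class ComparisonResult:
    """Replicate-level AICc comparison in the shape of the paper-style table."""

    model_names: list
    aicc_matrix: np.ndarray
    fits: list
    mk_rates: list = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return np.vstack([akaike_weights(r) for r in self.aicc_matrix])

    @property
    def mean_weights(self) -> np.ndarray:
        return self.weights.mean(axis=0)

    @property
    def best_model(self) -> str:
        mean_aicc = self.aicc_matrix.mean(axis=0)
        ks = [self.fits[0][j].k for j in range(len(self.model_names))]
        order = sorted(range(len(self.model_names)),
                       key=lambda j: (mean_aicc[j], ks[j]))
        return self.model_names[order[0]]

    @property
    def supported(self) -> list:
        d = self.aicc_matrix.mean(axis=0)
        d = d - d.min()
        return [m for m, dd in zip(self.model_names, d) if dd < 2.0]

    def best_fits(self) -> list:
        j = self.model_names.index(self.best_model)
        return [fits[j] for fits in self.fits]

    def table(self) -> pd.DataFrame:
        mean_aicc = self.aicc_matrix.mean(axis=0)
        return pd.DataFrame({
            "model": self.model_names,
            "mean_AICc": mean_aicc,
            "dAICc": mean_aicc - mean_aicc.min(),
            "mAICcW": self.mean_weights,
        })


# --------------------------------------------------------------- run: multi

def run_multivariate(config: RunConfig):
    """Size-correct, PCA, simmap, fit all families on retained PC scores.

    Returns ``(ComparisonResult, dict)`` where the dict carries the PCA,
    mean half-lives of the best model, and the manifest.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(config.echo(), seed=config.seed)
    trees, table, masses, categories = _resolve_inputs(config)
    ratios = log_shape_ratios(table, masses)
    pcs = pca(ratios)
    if config.n_pcs > pcs.n_components:
        raise ValueError("more retained PCs than traits")
    scores = pcs.scores.iloc[:, :config.n_pcs]
    manifest.timings["prepare"] = time.time() - t0

    trees = [_restrict_tree(t, ratios.species) for t in trees]
    if config.n_trees < len(trees):
        idx = rng.choice(len(trees), size=config.n_trees, replace=False)
        trees = [trees[i] for i in idx]
    t1 = time.time()
    names, aiccs, fits, q_hats = _fit_replicates(
        trees, scores, categories, config.families, config.maps_per_tree, rng)
    manifest.timings["fit"] = time.time() - t1
    comp = ComparisonResult(names, aiccs, fits, q_hats)

    best = comp.best_fits()
    hl = np.array([f.half_lives for f in best])
    extra = {
        "pca": pcs,
        "variance_fractions": pcs.variance_fractions,
        "ratios": ratios,
        "mean_half_life": float(np.mean(hl[np.isfinite(hl)]))
        if np.isfinite(hl).any() else np.inf,
        "per_pc_half_life": np.where(np.isfinite(hl), hl, np.nan).mean(axis=0)
        if len(best) else None,
        "manifest": manifest,
    }
    _emit(config, manifest, comp.table(), "multivariate")
    return comp, extra


# ----------------------------------------------------------------- run: uni

def format_optima_ordering(theta: dict, ci: dict | None = None,
                           tol: float = 0.0) -> str:
    """Render optima as an ordering string, e.g. ``ground<arb+glide<bat``.

    Regimes appear in canonical ground -> flyer order; successive optima are
    joined by ``<``/``>`` or by ``~`` when their confidence intervals
    overlap (or their difference is within ``tol`` when no CIs are given).
    """
    def rank(regime):
        return min(CATEGORIES.index(c) for c in regime.split("+"))

    def short(regime):
        return "+".join(_SHORT[c] for c in regime.split("+"))

    regimes = sorted(theta, key=rank)
    parts = [short(regimes[0])]
    for a, b in zip(regimes, regimes[1:]):
        ta, tb = float(np.ravel(theta[a])[0]), float(np.ravel(theta[b])[0])
        tie = abs(ta - tb) <= tol
        if ci and a in ci and b in ci:
            (la, ua), (lb, ub) = ci[a], ci[b]
            tie = (la <= ub) and (lb <= ua)
        parts.append("~" if tie else ("<" if ta < tb else ">"))
        parts.append(short(b))
    return "".join(parts)


def run_univariate(config: RunConfig):
    """Per-trait six-family comparison with bootstrap CIs for best OUM fits.

    Returns ``(summary DataFrame, dict of per-trait ComparisonResult,
    dict of per-trait BootstrapResult)``; the summary mirrors the shape of
    a per-trait best-model table (best model, optima ordering, alpha,
    half-life).
    """
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(config.echo(), seed=config.seed)
    trees, table, masses, categories = _resolve_inputs(config)
    ratios = log_shape_ratios(table, masses)
    trees = [_restrict_tree(t, ratios.species) for t in trees]
    if config.n_trees < len(trees):
        idx = rng.choice(len(trees), size=config.n_trees, replace=False)
        trees = [trees[i] for i in idx]

    rows, comparisons, boots = [], {}, {}
    for trait in ratios.ratios.columns:
        y = ratios.ratios[trait].to_dict()
        names, aiccs, fits, q_hats = _fit_replicates(
            trees, y, categories, config.families, config.maps_per_tree, rng)
        comp = ComparisonResult(names, aiccs, fits, q_hats)
        comparisons[trait] = comp
        best_name = comp.best_model
        j = names.index(best_name)
        best_fit = comp.fits[0][j]
        row = {"trait": trait, "best_model": best_name,
               "mAICcW": float(comp.mean_weights[j])}
        if best_name.startswith("OUM") or best_name == "OU1":
            alpha = float(np.ravel(best_fit.alpha)[0])
            row["alpha"] = alpha
            row["half_life"] = float(np.log(2) / alpha) if alpha > 0 else np.inf
        else:
            row["alpha"] = np.nan
            row["half_life"] = np.nan
        if best_name.startswith("OUM"):
            scheme = best_name.split("_", 1)[1]
            # pool this scheme's maps across replicate trees for the bootstrap
            pool = []
            for tree in trees:
                painted = paint_scheme(categories, scheme)
                tip_states = {lab: painted[lab] for lab in tree.tip_labels}
                mk = fit_mk_er(tree, tip_states)
                pool.extend((tree, m) for m in sample_simmap(
                    tree, tip_states, mk, config.maps_per_tree,
                    seed=int(rng.integers(2 ** 31))))
            # bootstrap on the first tree's maps (maps are tree-specific)
            tree0 = trees[0]
            maps0 = [m for t, m in pool if t is tree0]
            boot = bootstrap_optima(tree0, maps0, best_fit,
                                    n_maps=config.bootstrap_maps,
                                    reps_per_map=config.bootstrap_reps,
                                    seed=int(rng.integers(2 ** 31)))
            boots[trait] = boot
            ci = {r: boot.ci[f"theta[{r}]"] for r in best_fit.theta
                  if f"theta[{r}]" in boot.ci}
            row["theta_order"] = format_optima_ordering(best_fit.theta, ci)
        elif best_name == "OU1":
            row["theta_order"] = "--"
        else:
            row["theta_order"] = "--"
        rows.append(row)
    summary = pd.DataFrame(rows)
    _emit(config, manifest, summary, "univariate")
    return summary, comparisons, boots


# ------------------------------------------------------------- run: fossils

def run_with_fossils(config: RunConfig):
    """Multivariate comparison on a fossil-grafted, non-ultrametric tree.

    Grafts the configured fossils as a polytomy with the host clade's stem,
    imputes their masses from extant-flyer allometry, pushes them through
    the identical size-correction path, and fits all families on simmaps of
    the single grafted tree.  Optima larger than 10x the observed trait
    range are flagged in the manifest (a known artifact regime of
    extant+extinct multivariate fits).
    """
    if config.fossils is None or not config.fossils.names:
        return run_multivariate(config)
    rng = np.random.default_rng(config.seed)
    manifest = RunManifest(config.echo(), seed=config.seed)
    trees, table, masses, categories = _resolve_inputs(config)
    fs = config.fossils

    flyer_species = [sp for sp, c in categories.items() if c == fs.category
                     and sp in set(table.data["species"])]
    extant_flyers = TraitTable(
        table.data[table.data["species"].isin(flyer_species)].copy(), table.traits)
    fossil_masses = estimate_fossil_mass(
        extant_flyers, masses[masses.index.isin(flyer_species)],
        fs.measurements.loc[fs.names, list(table.traits)])

    fossil_rows = fs.measurements.loc[fs.names, list(table.traits)].copy()
    fossil_rows.insert(0, "species", fs.names)
    fossil_rows["extinct"] = True
    merged = TraitTable(
        pd.concat([table.data, fossil_rows], ignore_index=True), table.traits)
    all_masses = pd.concat([masses, fossil_masses])
    all_categories = dict(categories, **{f: fs.category for f in fs.names})

    tree = _restrict_tree(trees[0], [sp for sp in merged.species
                                     if sp not in fs.names])
    grafted = graft_fossil_clade(tree, fs.host_clade, fs.names,
                                 fs.stem_age, fs.tip_ages)

    ratios = log_shape_ratios(merged, all_masses)
    pcs = pca(ratios)
    scores = pcs.scores.iloc[:, :config.n_pcs]
    names, aiccs, fits, q_hats = _fit_replicates(
        [grafted], scores, all_categories, config.families,
        config.fossil_maps, rng)
    comp = ComparisonResult(names, aiccs, fits, q_hats)

    # flag implausible optima (|theta| > 10x the observed score range)
    ranges = scores.max() - scores.min()
    flags = []
    for f in comp.best_fits():
        for regime, th in f.theta.items():
            th = np.atleast_1d(np.asarray(th, float))
            if np.any(np.abs(th) > 10 * ranges.to_numpy()[:len(th)]):
                flags.append(f"optimum for {regime!r} exceeds 10x trait range")
    manifest.warnings.extend(sorted(set(flags)))

    best = comp.best_fits()
    hl = np.array([f.half_lives for f in best])
    extra = {
        "pca": pcs,
        "tree": grafted,
        "fossil_masses": fossil_masses,
        "ratios": ratios,
        "mean_half_life": float(np.mean(hl[np.isfinite(hl)]))
        if np.isfinite(hl).any() else np.inf,
        "manifest": manifest,
        "optima_flags": sorted(set(flags)),
    }
    _emit(config, manifest, comp.table(), "fossil")
    return comp, extra


# ------------------------------------------------------------------ outputs

def _emit(config: RunConfig, manifest: RunManifest, table: pd.DataFrame,
          stage: str):
    if not config.outdir:
        return
    import pathlib
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / f"{stage}_comparison.tsv"
    table.to_csv(tsv, sep="\t", index=False)
    manifest.add_output(tsv)
    mpath = out / f"{stage}_manifest.json"
    manifest.write(mpath)
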