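"""Orchestration: feature table -> alternative classification trees per
species -> comparison and prevalence reports.

Each species is modelled three times, with exactly one human-introduction
surrogate (visibility, road density, or urban ratio) alongside the five
shared environmental factors (river density at the 500 m buffer,
connectivity, pond area, chlorophyll-a, drainage).  Evaluation is apparent
error: the modal optimal tree is scored on the full dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cart
from .cart import CartParams, ClassificationTree, ModelEvaluation

log = logging.getLogger("pondsight")


def pct(k: float, n: float) -> int:
    """Display percentage, rounded half up (62.5% prints as 63)."""
    return int(np.floor(100.0 * k / n + 0.5))

INDICATORS = {
    "visibility": "visibility",
    "road_density": "road_density_1e-3_m_per_m2",
    "urban_ratio": "urban_ratio",
}
SHARED_FACTORS = [
    "river_density_500m_1e-3_m_per_m2",
    "connectivity",
    "area_m2",
    "chl_a_ug_per_L",
    "drained",
]
SPECIES_COLUMNS = {"bluegill": "present_bluegill", "bass": "present_bass"}
CATEGORICAL = ("connectivity",)


@dataclass
class StudyConfig:
    """Knobs of the statistical stage."""

    cart_params: CartParams = field(default_factory=CartParams)
    k_folds: int = 10
    n_repeats: int = 50
    base_seed: int = 0
    species: tuple[str, ...] = ("bluegill", "bass")
    indicators: tuple[str, ...] = ("visibility", "road_density", "urban_ratio")
    river_buffer: int = 500

    def __post_init__(self) -> None:
        unknown = set(self.indicators) - set(INDICATORS)
        if unknown:
            raise ValueError(f"unknown indicators: {sorted(unknown)}")


@dataclass
class ComparisonRow:
    species: str
    indicator: str
    tree: ClassificationTree
    evaluation: ModelEvaluation

    def summary(self) -> dict:
        ev = self.evaluation
        return {
            "species": self.species,
            "indicator": self.indicator,
            "n_leaves": self.tree.n_leaves(),
            "split_variables": "|".join(self.tree.split_variables()),
            "misclassification_pct": ev.misclassification_pct,
            "misclassification": ev.misclassification,
            "sensitivity": round(ev.sensitivity, 2) if ev.tp + ev.fn else float("nan"),
            "specificity": round(ev.specificity, 2) if ev.tn + ev.fp else float("nan"),
        }


def predictor_frame(features: pd.DataFrame, indicator: str, river_buffer: int = 500) -> pd.DataFrame:
    shared = [c.replace("_500m_", f"_{river_buffer}m_") for c in SHARED_FACTORS]
    cols = [INDICATORS[indicator]] + shared
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    return features[cols]


def run_indicator_comparison(
    features: pd.DataFrame, species: str, config: StudyConfig | None = None
) -> list[ComparisonRow]:
    """Fit the modal optimal tree once per surrogate indicator and score it
    on the full dataset."""
    config = config or StudyConfig()
    ycol = SPECIES_COLUMNS[species]
    if ycol not in features.columns:
        raise ValueError(f"missing response column {ycol!r}")
    y = features[ycol].to_numpy().astype(int)
    rows = []
    for indicator in config.indicators:
        X = predictor_frame(features, indicator, config.river_buffer)
        tree = cart.modal_optimal_tree(
            X,
            y,
            config.cart_params,
            n_repeats=config.n_repeats,
            base_seed=config.base_seed,
            k=config.k_folds,
            categorical=CATEGORICAL,
        )
        ev = cart.evaluate(tree, y, X)
        rows.append(ComparisonRow(species, indicator, tree, ev))
        log.info(
            "%s / %s: %d leaves, misclassification %d%%",
            species,
            indicator,
            tree.n_leaves(),
            ev.misclassification_pct,
        )
    return rows


def prevalence_summary(labels: pd.DataFrame, species: tuple[str, ...] = ("bluegill", "bass")) -> dict:
    """Per-species presence counts and percentages plus the species-overlap
    breakdown (only A / only B / both / neither, and the union percentage)."""
    n = len(labels)
    out: dict = {"n_ponds": n}
    present = {}
    for sp in species:
        col = SPECIES_COLUMNS[sp]
        present[sp] = labels[col].to_numpy().astype(bool)
        out[f"n_present_{sp}"] = int(present[sp].sum())
        out[f"pct_present_{sp}"] = pct(present[sp].sum(), n)
    if len(species) == 2:
        a, b = (present[sp] for sp in species)
        out["n_only_first"] = int((a & ~b).sum())
        out["n_only_second"] = int((~a & b).sum())
        out["n_both"] = int((a & b).sum())
        out["n_neither"] = int((~a & ~b).sum())
        union = int((a | b).sum())
        out["n_union"] = union
        out["pct_union"] = pct(union, n)
    return out


def prevalence_from_counts(n_only_first: int, n_only_second: int, n_both: int, n_total: int) -> dict:
    """Prevalence summary from printed overlap counts rather than labels."""
    rows = (
        [{"present_bluegill": 1, "present_bass": 0}] * n_only_first
        + [{"present_bluegill": 0, "present_bass": 1}] * n_only_second
        + [{"present_bluegill": 1, "present_bass": 1}] * n_both
        + [{"present_bluegill": 0, "present_bass": 0}]
        * (n_total - n_only_first - n_only_second - n_both)
    )
    return prevalence_summary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# tree reports and the full run
# ---------------------------------------------------------------------------


# ---------------------------------------------------------------------------
# planted-rule recovery trials (synthetic end-to-end experiment)
# ---------------------------------------------------------------------------


@dataclass
class PlantedTrial:
    """One end-to-end run on a synthetic landscape with known planted rules."""

    seed: int
    planted_visibility_threshold: float
    planted_chl_threshold: float
    prevalence: dict
    misclassification: dict  # (species, indicator) -> exact fraction
    split_variables: dict  # (species, indicator) -> tuple of variables
    recovered_a: bool  # bluegill tree splits on exactly {connectivity, visibility}
    recovered_b: bool  # bass tree splits on exactly {chl_a}
    vis_threshold_in_gap: bool | None  # None when species A did not recover
    chl_threshold_in_gap: bool | None


def threshold_in_gap(values: np.ndarray, planted: float, learned: float) -> bool:
    """True when the learned threshold lies in the observed-data gap that
    brackets the planted threshold."""
    values = np.asarray(values, dtype=float)
    below = values[values < planted]
    above = values[values >= planted]
    if below.size == 0 or above.size == 0:
        return False
    return bool(below.max() < learned <= above.min())


def _split_threshold(tree: ClassificationTree, variable: str) -> float | None:
    def walk(node):
        if node.is_leaf:
            return None
        if node.split.variable == variable and node.split.kind == "numeric":
            return node.split.threshold
        found = walk(node.children[0])
        return found if found is not None else walk(node.children[1])

    return walk(tree.root)


def run_planted_trial(seed: int, n_ponds: int = 200, n_repeats: int = 50) -> PlantedTrial:
    """Generate a coarse synthetic study landscape, run the full analysis for
    both species and all three indicators, and score recovery of the planted
    rules."""
    from .synthetic_data import SyntheticConfig, generate_study_dataset

    cfg = SyntheticConfig.coarse(seed=seed, n_ponds=n_ponds)
    _, features, rules = generate_study_dataset(cfg)
    study = StudyConfig(n_repeats=n_repeats, base_seed=seed)
    mis, split_vars, trees = {}, {}, {}
    for species in ("bluegill", "bass"):
        for row in run_indicator_comparison(features, species, study):
            mis[(species, row.indicator)] = row.evaluation.misclassification
            split_vars[(species, row.indicator)] = tuple(row.tree.split_variables())
            trees[(species, row.indicator)] = row.tree
    tree_a = trees[("bluegill", "visibility")]
    tree_b = trees[("bass", "visibility")]
    recovered_a = set(tree_a.split_variables()) == {"connectivity", "visibility"}
    recovered_b = set(tree_b.split_variables()) == {"chl_a_ug_per_L"}
    vis_gap = chl_gap = None
    if recovered_a:
        thr = _split_threshold(tree_a, "visibility")
        vis_gap = threshold_in_gap(
            features["visibility"].to_numpy(), rules.visibility_threshold, thr
        )
    if recovered_b:
        thr = _split_threshold(tree_b, "chl_a_ug_per_L")
        chl_gap = threshold_in_gap(
            features["chl_a_ug_per_L"].to_numpy(), rules.chl_threshold, thr
        )
    return PlantedTrial(
        seed=seed,
        planted_visibility_threshold=rules.visibility_threshold,
        planted_chl_threshold=rules.chl_threshold,
        prevalence=prevalence_summary(features),
        misclassification=mis,
        split_variables=split_vars,
        recovered_a=recovered_a,
        recovered_b=recovered_b,
        vis_threshold_in_gap=vis_gap,
        chl_threshold_in_gap=chl_gap,
    )


def summarize_trials(trials: list[PlantedTrial]) -> dict:
    """Aggregate recovery and indicator-ordering fractions over trials."""
    n = len(trials)
    ordered = [
        t.misclassification[("bluegill", "visibility")]
        <= t.misclassification[("bluegill", "road_density")]
        <= t.misclassification[("bluegill", "urban_ratio")]
        for t in trials
    ]
    tied_b = [
        len({t.misclassification[("bass", ind)] for ind in ("visibility", "road_density", "urban_ratio")}) == 1
        for t in trials
    ]
    rec_a = [t.recovered_a for t in trials]
    rec_b = [t.recovered_b for t in trials]
    gaps_a = [t.vis_threshold_in_gap for t in trials if t.vis_threshold_in_gap is not None]
    gaps_b = [t.chl_threshold_in_gap for t in trials if t.chl_threshold_in_gap is not None]
    return {
        "n_trials": n,
        "frac_recovered_bluegill": sum(rec_a) / n,
        "frac_recovered_bass": sum(rec_b) / n,
        "frac_vis_threshold_in_gap": (sum(gaps_a) / len(gaps_a)) if gaps_a else float("nan"),
        "frac_chl_threshold_in_gap": (sum(gaps_b) / len(gaps_b)) if gaps_b else float("nan"),
        "frac_indicator_ordering_bluegill": sum(ordered) / n,
        "frac_indicator_tie_bass": sum(tied_b) / n,
        "mean_misclassification_pct": {
            f"{sp}_{ind}": round(
                100 * float(np.mean([t.misclassification[(sp, ind)] for t in trials])), 1
            )
            for sp in ("bluegill", "bass")
            for ind in ("visibility", "road_density", "urban_ratio")
        },
    }


def tree_report(tree: ClassificationTree) -> dict:
    """JSON-serialisable description of a tree: nodes, splits, class
    fractions, improvements, and the pruning/CV metadata."""

    def node_dict(node) -> dict:
        n0, n1 = node.class_counts
        d = {
            "id": node.node_id,
            "n": node.n,
            "class_counts": [n0, n1],
            "fraction_present": n1 / node.n,
            "predicted": node.predicted_class,
        }
        if not node.is_leaf:
            d["split"] = node.split.describe()
            d["improvement"] = node.improvement
            d["children"] = [node_dict(c) for c in node.children]
        return d

    report = {
        "n": tree.n,
        "n_leaves": tree.n_leaves(),
        "columns": tree.columns,
        "root": node_dict(tree.root),
        "pruning_sequence": [
            {"alpha": a, "n_leaves": s, "rel_error": e} for a, s, e in tree.pruning_sequence
        ],
    }
    if tree.modal_size is not None:
        report["modal_size"] = tree.modal_size
        report["size_counts"] = tree.size_counts
        report["first_split_counts"] = tree.first_split_counts
    return report


def render_tree(tree: ClassificationTree) -> str:
    """Text rendering of a tree, one node per line."""
    lines = []

    def walk(node, indent: int, label: str) -> None:
        n0, n1 = node.class_counts
        head = f"{'  ' * indent}{label}n={node.n} absent={n0} present={n1}"
        if node.is_leaf:
            lines.append(f"{head} -> predict {'present' if node.predicted_class else 'absent'}")
        else:
            lines.append(f"{head} | {node.split.describe()} (improvement {node.improvement:.2f})")
            walk(node.children[0], indent + 1, "[L] ")
            walk(node.children[1], indent + 1, "[R] ")

    walk(tree.root, 0, "")
    return "\n".join(lines)


def run_full_pipeline(
    features: pd.DataFrame, out_dir, config: StudyConfig | None = None
) -> Path:
    """Fit all species x indicator trees, write features.csv, per-tree
    reports, cptables, comparison.csv, prevalence.csv and a run log."""
    config = config or StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features.to_csv(out / "features.csv", index=False)
    comparison_rows = []
    for species in config.species:
        try:
            rows = run_indicator_comparison(features, species, config)
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"stage tree-fitting ({species}) failed: {exc}") from exc
        for row in rows:
            stem = f"tree_{species}_{row.indicator}"
            with open(out / f"{stem}.json", "w", encoding="utf-8") as fh:
                json.dump(tree_report(row.tree), fh, indent=1)
            (out / f"{stem}.txt").write_text(render_tree(row.tree) + "\n", encoding="utf-8")
            pd.DataFrame(
                row.tree.pruning_sequence, columns=["alpha", "n_leaves", "rel_error"]
            ).to_csv(out / f"cptable_{species}_{row.indicator}.csv", index=False)
            comparison_rows.append(row.summary())
    pd.DataFrame(comparison_rows).to_csv(out / "comparison.csv", index=False)
    prev = prevalence_summary(features, config.species)
    pd.DataFrame([prev]).to_csv(out / "prevalence.csv", index=False)
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "base_seed": config.base_seed,
                "n_repeats": config.n_repeats,
                "k_folds": config.k_folds,
                "cart_params": vars(config.cart_params),
                "indicators": list(config.indicators),
                "species": list(config.species),
                "river_buffer": config.river_buffer,
            },
            fh,
            indent=1,
        )
    return out
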