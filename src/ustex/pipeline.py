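"""End-to-end orchestration of the two experiments.

``run_variability_study`` chains simulate -> extract -> select -> evaluate
-> statistics and reports per-expert performance, the two-way ANOVA
(expert x feature-selection round), Tukey pairs, the two expert-transfer
scenarios with Kruskal-Wallis tests, and the ROI-position analysis.
``run_texture_validation`` runs the tile-classification harness on
synthetic texture banks.

Presets scale problem sizes (cohort, iterations, rounds, repeats), never
the algorithms:

* ``default`` — the full study design (125 patients, 5 iterations,
  20 selection rounds, 10x10-fold CV); hours of compute.
* ``ci`` — 48 patients, 5 iterations, 5 rounds, 3 repeats; a few minutes.
* ``mini`` — 40 patients, 3 iterations, 3 rounds, 3 repeats and fewer
  frames per patient; ~20 s, used for seed sweeps.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .evaluate import (
    minmax_normalize,
    repeated_cv,
    scenario_cross_expert,
    scenario_same_expert,
)
from .features import default_registry, extract_all
from .selection import InstanceSet, selection_protocol
from .simulate import (
    Cohort,
    FrameGeometryConfig,
    SyntheticCohortConfig,
    TextureParams,
    default_profiles,
    generate_cohort,
    generate_texture_bank,
    tile_nonoverlapping,
)
from .stats import (
    kruskal_wallis,
    position_effect_report,
    tukey_hsd,
    two_way_anova,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Everything one variability-study run depends on."""

    seed: int = 0
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    geometry: FrameGeometryConfig = field(default_factory=FrameGeometryConfig)
    texture: TextureParams = field(default_factory=TextureParams)
    iterations: int = 5
    k: int = 10
    rounds: int = 20
    folds: int = 10
    repeats: int = 10
    alpha: float = 0.01
    alpha_secondary: float = 0.05


def preset_config(name: str, seed: int = 0) -> StudyConfig:
    """Named problem-size presets (see module docstring)."""
    if name == "default":
        return StudyConfig(seed=seed)
    if name == "ci":
        return StudyConfig(
            seed=seed,
            cohort=SyntheticCohortConfig(n_f0=20, n_f4=28),
            iterations=5,
            rounds=5,
            repeats=3,
        )
    if name == "mini":
        return StudyConfig(
            seed=seed,
            cohort=SyntheticCohortConfig(
                n_f0=16, n_f4=24, frames_mean=5, frames_sd=2,
                frames_min=2, frames_max=8,
            ),
            iterations=3,
            rounds=3,
            repeats=3,
        )
    raise ValueError(f"unknown preset {name!r}")


def cohort_instance_sets(cohort: Cohort) -> list[InstanceSet]:
    """Extract the 234 texture features of every ROI, one instance set per
    (expert, iteration)."""
    registry = default_registry()
    sets = []
    for (expert, iteration), rois in sorted(cohort.roi_sets.items()):
        if not rois:
            continue
        feats = np.array([extract_all(r.patch) for r in rois])
        labels = np.array(
            [1 if cohort.labels[r.patient_id] == "F4" else 0 for r in rois]
        )
        sets.append(
            InstanceSet(
                set_id=(expert, iteration),
                features=feats,
                labels=labels,
                patient_ids=tuple(r.patient_id for r in rois),
                feature_names=registry.names,
            )
        )
    return sets


def _roi_position_means(cohort: Cohort) -> dict[tuple[int, int], dict]:
    out = {}
    for key, rois in cohort.roi_sets.items():
        if not rois:
            continue
        out[key] = {
            "mean_rho": float(np.mean([r.center_polar[0] for r in rois])),
            "mean_theta": float(np.mean([r.center_polar[1] for r in rois])),
            "mean_ox": float(np.mean([r.center_xy[0] for r in rois])),
            "mean_oy": float(np.mean([r.center_xy[1] for r in rois])),
        }
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run_variability_study(config: StudyConfig) -> dict:
    """Run the full expert-variability experiment and return the report.

    The report carries a manifest (every seed and parameter), per-expert
    ROI counts and AUROC summaries, the two-way ANOVA and Tukey pairs, the
    two transfer scenarios with Kruskal-Wallis tests, and the ROI-position
    analysis.  Two runs with the same config are identical.
    """
    t_start = time.time()
    master = np.random.default_rng(config.seed)
    cohort_rng, select_rng, cv_rng = master.spawn(3)

    logger.info("simulating cohort (%d patients)", config.cohort.n_patients)
    cohort = generate_cohort(
        config.cohort,
        profiles=default_profiles(),
        geometry=config.geometry,
        params=config.texture,
        rng=cohort_rng,
        iterations=config.iterations,
    )
    roi_counts = {
        e: float(
            np.mean(
                [
                    len(cohort.roi_sets[(e, z)])
                    for z in range(1, config.iterations + 1)
                ]
            )
        )
        for e in sorted({k[0] for k in cohort.roi_sets})
    }

    logger.info("extracting features")
    sets = cohort_instance_sets(cohort)

    logger.info("running %d selection rounds (k=%d)", config.rounds, config.k)
    rounds = selection_protocol(sets, k=config.k, rounds=config.rounds, rng=select_rng)

    logger.info("repeated cross-validation")
    rows = []
    positions = _roi_position_means(cohort)
    for rnd in rounds:
        for sid, fset in sorted(rnd.filtered_sets.items()):
            try:
                ev = repeated_cv(
                    fset,
                    folds=config.folds,
                    repeats=config.repeats,
                    rng=cv_rng,
                    round_index=rnd.round_index,
                )
            except ValueError as exc:  # set too small for CV at this size
                logger.warning("skipping %s in round %d: %s", sid, rnd.round_index, exc)
                continue
            rows.append(
                {
                    "expert": sid[0],
                    "iteration": sid[1],
                    "round": rnd.round_index,
                    "auroc": ev.mean_auroc,
                    "auroc_sd": ev.sd_auroc,
                    **positions[sid],
                }
            )
    table = pd.DataFrame(rows)

    logger.info("statistics")
    # the ANOVA needs every expert x round cell filled; an expert whose
    # sets were too small for CV in some round is left out and reported
    cell_counts = pd.crosstab(table["expert"], table["round"])
    complete = cell_counts.index[(cell_counts > 0).all(axis=1)]
    anova_excluded = sorted(set(table["expert"]) - set(complete))
    anova_table = table[table["expert"].isin(complete)]
    anova = two_way_anova(anova_table, "auroc", "expert", "round")
    tukey = tukey_hsd(
        anova_table["auroc"].to_numpy(), anova_table["expert"].to_numpy()
    )
    per_expert = {
        int(e): {
            "mean_auroc": float(g["auroc"].mean()),
            "sd_auroc": float(g["auroc"].std(ddof=1)),
        }
        for e, g in table.groupby("expert")
    }

    # scenario 1: same expert, other iterations (automatic expert excluded
    # because its fixed placement re-selects the same patients)
    same_rows = []
    cross_rows = []
    for rnd in rounds:
        fsets = rnd.filtered_sets
        for e in sorted({k[0] for k in fsets}):
            if e == 5:
                continue
            by_iter = {z: s for (ee, z), s in fsets.items() if ee == e}
            if len(by_iter) < 2:
                continue
            for rec in scenario_same_expert(by_iter):
                same_rows.append({"expert": e, "round": rnd.round_index, **rec})
        for rec in scenario_cross_expert(dict(fsets)):
            cross_rows.append({"round": rnd.round_index, **rec})
    same_df = pd.DataFrame(same_rows)
    cross_df = pd.DataFrame(cross_rows)

    kw_same = kruskal_wallis(
        [g["auroc"].to_numpy() for _, g in same_df.groupby("expert")]
    )
    kw_cross = kruskal_wallis(
        [g["auroc"].to_numpy() for _, g in cross_df.groupby("train_expert")]
    )

    # position analysis over per-(expert, iteration) mean AUROC
    pos_table = (
        table.groupby(["expert", "iteration"])
        .agg(
            auroc=("auroc", "mean"),
            mean_rho=("mean_rho", "first"),
            mean_theta=("mean_theta", "first"),
            mean_ox=("mean_ox", "first"),
            mean_oy=("mean_oy", "first"),
        )
        .reset_index()
    )
    position = position_effect_report(
        pos_table, alpha=config.alpha, alpha_secondary=config.alpha_secondary
    )

    report = {
        "manifest": {
            "seed": config.seed,
            "config": asdict(config),
            "n_instance_sets": len(sets),
            "runtime_s": round(time.time() - t_start, 1),
        },
        "roi_counts": roi_counts,
        "exclusions": {
            str(k): list(v) for k, v in sorted(cohort.exclusions.items())
        },
        "per_expert": per_expert,
        "anova": anova,
        "anova_flags": {
            "expert_significant": bool(anova["expert"]["p"] < config.alpha),
            "selection_significant": bool(anova["round"]["p"] < config.alpha),
            "excluded_experts": anova_excluded,
        },
        "tukey": tukey,
        "scenario_same_expert": {
            "kruskal_wallis": {"H": kw_same[0], "p": kw_same[1]},
            "mean_auroc": float(same_df["auroc"].mean()),
            "per_expert_mean": {
                int(e): float(g["auroc"].mean())
                for e, g in same_df.groupby("expert")
            },
        },
        "scenario_cross_expert": {
            "kruskal_wallis": {"H": kw_cross[0], "p": kw_cross[1]},
            "mean_auroc": float(cross_df["auroc"].mean()),
            # human-expert pairs only: comparable with scenario 1, which
            # excludes the automatic expert (its fixed placement re-selects
            # the same patients and would inflate the same-expert reading)
            "mean_auroc_humans": float(
                cross_df.loc[
                    (cross_df["train_expert"] != 5)
                    & (cross_df["test_expert"] != 5),
                    "auroc",
                ].mean()
            ),
            "per_train_expert_mean": {
                int(e): float(g["auroc"].mean())
                for e, g in cross_df.groupby("train_expert")
            },
        },
        "position": position,
        "auroc_table": table,
    }
    return _jsonable(report)


def run_texture_validation(
    n_classes: int = 5,
    seed: int = 0,
    folds: int = 10,
    image_size: int = 640,
    images: list[np.ndarray] | None = None,
) -> dict:
    """Tile-classification validation of the texture suite.

    Each texture image is cut into non-overlapping 64x64 tiles; a
    multinomial logistic model must recover the source image of each tile
    under stratified CV.  ``images`` may supply externally provided
    textures in place of the synthetic bank.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    rng = np.random.default_rng(seed)
    if images is None:
        images = generate_texture_bank(n_classes, rng, image_size=image_size)
    if len(images) < 2:
        raise ValueError("need at least 2 texture classes")

    X_parts, y_parts = [], []
    for cls, img in enumerate(images):
        tiles = tile_nonoverlapping(img, 64)
        X_parts.append(np.array([extract_all(t) for t in tiles]))
        y_parts.append(np.full(len(tiles), cls))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)

    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        tr, te, _ = minmax_normalize(X[train_idx], X[test_idx])
        model = LogisticRegression(max_iter=2000)
        model.fit(tr, y[train_idx])
        correct += int((model.predict(te) == y[test_idx]).sum())
    accuracy = correct / len(y)
    return {
        "n_classes": len(images),
        "n_tiles": int(len(y)),
        "tiles_per_image": int(len(y) / len(images)),
        "accuracy": float(accuracy),
    }
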