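"""Bayesian inverse prediction of subject traits from stride features.

Linear Gaussian models (conjugate Bayesian regression, identity link) are
trained on strides of normally-grown (AGA) animals to predict the walker's
body mass, linear size (PC1 of log segmental measures), and age from 34
stride features: sex, 9 dimensionless spatiotemporal variables, 12
postural variables (6 mean joint angles + 6 amplitudes), and 12
coordination components (PCA of the pooled Fourier shape coefficients,
loadings frozen from the training set).  Applying the trained models to
strides of growth-restricted (SGA) animals and comparing predictions with
the walkers' actual traits quantifies whether their locomotion "looks"
like that of a larger, older, or younger animal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import ConjugateLinearModel
from .errors import DomainError
from .kinematics import (
    JOINTS,
    JointTrace,
    affine_split,
    coordination_pca,
    fourier_decompose,
    shape_matrix_from_descriptors,
)

__all__ = [
    "FEATURE_NAMES",
    "size_score",
    "stride_descriptors",
    "build_feature_table",
    "assemble_features",
    "PosteriorModel",
    "train",
    "predict",
    "validate",
    "compare_predictions",
    "age_stall_experiment",
]

SPATIOTEMPORAL = (
    "froude_speed",
    "rel_stride_length",
    "rel_step_fore",
    "rel_step_hind",
    "rel_frequency",
    "duty_factor",
    "duty_factor_hind",
    "phase_diagonal",
    "phase_ipsilateral",
)
POSTURAL = tuple(f"mean_{j}" for j in JOINTS) + tuple(f"amp_{j}" for j in JOINTS)
COORDINATION = tuple(f"pc{k}" for k in range(1, 13))

#: fixed feature ordering: sex, 9 spatiotemporal, 12 postural, 12 coordination
FEATURE_NAMES = ("sex",) + SPATIOTEMPORAL + POSTURAL + COORDINATION
assert len(FEATURE_NAMES) == 34


# ---------------------------------------------------------------- size score

def size_score(piglets: pd.DataFrame) -> pd.Series:
    """Linear size per piglet: PC1 of the log segmental-length matrix.

    Columns named ``seg_*_m`` are used.  Zero-variance columns are dropped
    with a warning; the sign is fixed so that larger animals score higher.
    Identical animals all score 0.
    """
    seg_cols = [c for c in piglets.columns if c.startswith("seg_")]
    if len(seg_cols) < 2:
        raise DomainError("need at least 2 segment columns")
    X = np.log(piglets[seg_cols].to_numpy(dtype=float))
    keep = X.std(axis=0) > 0
    if not keep.any():
        warnings.warn("all segment columns are zero-variance; scores are 0",
                      stacklevel=2)
        return pd.Series(0.0, index=piglets["piglet_id"].to_numpy(), name="size_score")
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance segment column(s)",
                      stacklevel=2)
        X = X[:, keep]
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = vt[0]
    if pc1.sum() < 0:  # larger animal -> larger log lengths -> higher score
        pc1 = -pc1
    scores = Xc @ pc1
    return pd.Series(scores, index=piglets["piglet_id"].to_numpy(), name="size_score")


# ---------------------------------------------------------------- assembling

def stride_descriptors(joint_traces: pd.DataFrame) -> dict:
    """Fourier descriptors per stride: stride_id -> {joint: FourierDescriptor}."""
    out = {}
    for (sid, joint), grp in joint_traces.groupby(["stride_id", "joint"], sort=False):
        trace = JointTrace(joint, grp["cycle_fraction"].to_numpy(),
                           grp["angle_rad"].to_numpy())
        out.setdefault(sid, {})[joint] = affine_split(fourier_decompose(trace), joint)
    return out


def assemble_features(spatiotemporal, posture, coordination, sex) -> np.ndarray:
    """Assemble one stride's 34-feature vector in the fixed ordering.

    ``spatiotemporal`` and ``posture`` are mappings; ``coordination`` is a
    12-sequence of PC scores; ``sex`` is 0 (F) or 1 (M).
    """
    for block, keys in (("spatiotemporal", SPATIOTEMPORAL), ("postural", POSTURAL)):
        src = spatiotemporal if block == "spatiotemporal" else posture
        missing = [k for k in keys if k not in src]
        if missing:
            raise DomainError(f"missing {block} feature(s): {missing}")
    coord = np.asarray(coordination, dtype=float)
    if coord.shape != (12,):
        raise DomainError(f"coordination block must have 12 entries, got {coord.shape}")
    vec = np.concatenate(
        [
            [float(sex)],
            [float(spatiotemporal[k]) for k in SPATIOTEMPORAL],
            [float(posture[k]) for k in POSTURAL],
            coord,
        ]
    )
    if not np.isfinite(vec).all():
        raise DomainError("non-finite value in feature vector")
    return vec


def build_feature_table(
    norm_strides: pd.DataFrame,
    joint_traces: pd.DataFrame,
    piglets: pd.DataFrame,
    pca: dict = None,
    n_pcs: int = 12,
):
    """Per-stride 34-feature table plus targets.

    When ``pca`` is None the coordination loadings are fitted on the given
    strides and returned for reuse; otherwise the frozen loadings/centering
    are applied (as required when featurizing validation or SGA strides).

    Returns ``(features, pca)`` where ``features`` carries the 34 feature
    columns plus ``stride_id, piglet_id, category`` and the targets
    ``actual_mass, actual_size, actual_age``.
    """
    desc = stride_descriptors(joint_traces)
    ids = [sid for sid in norm_strides["stride_id"] if sid in desc]
    if not ids:
        raise DomainError("no strides with joint traces")
    shapes = shape_matrix_from_descriptors([desc[sid] for sid in ids])
    if pca is None:
        scores, loadings, evr = coordination_pca(shapes, n_pcs=n_pcs)
        pca = {
            "loadings": loadings,
            "center": shapes.mean(axis=0),
            "explained_variance_ratio": evr,
        }
    else:
        scores = (shapes - pca["center"]) @ pca["loadings"]

    sizes = size_score(piglets)
    masses = piglets.set_index("piglet_id")["birth_mass_kg"]
    st = norm_strides.set_index("stride_id").loc[ids]

    rows = []
    for i, sid in enumerate(ids):
        srow = st.loc[sid]
        posture = {}
        for j in JOINTS:
            posture[f"mean_{j}"] = desc[sid][j].mean_angle
            posture[f"amp_{j}"] = desc[sid][j].amplitude
        sex = 0.0 if srow["sex"] == "F" else 1.0
        vec = assemble_features(srow, posture, scores[i], sex)
        rec = dict(zip(FEATURE_NAMES, vec))
        rec.update(
            stride_id=sid,
            piglet_id=srow["piglet_id"],
            category=srow["category"],
            actual_mass=float(masses[srow["piglet_id"]]),
            actual_size=float(sizes[srow["piglet_id"]]),
            actual_age=float(srow["age_h"]),
        )
        rows.append(rec)
    return pd.DataFrame(rows), pca


# ------------------------------------------------------------------ modelling

@dataclass
class PosteriorModel:
    """A trained trait model: conjugate posterior plus training metadata."""

    target: str
    model: ConjugateLinearModel = field(repr=False)
    feature_names: tuple
    n_train: int
    seed: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        summ = self.model.coefficient_summary()
        return pd.DataFrame(
            {"feature": summ.names, "post_mean": summ.mean, "post_sd": summ.sd}
        )


def train(
    features,
    target_values,
    target: str = "mass",
    prior_config: dict = None,
    seed: int = 0,
) -> PosteriorModel:
    """Train a Bayesian linear trait model on stride features.

    ``features`` is an (n, 34) array or a DataFrame carrying the
    ``FEATURE_NAMES`` columns.  Priors: N(0, 1) on standardized
    coefficients, a vague prior on the intercept and residual scale
    (see :class:`~pigait.bayes.ConjugateLinearModel`); the posterior is
    closed form, so the seed is metadata only.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(target_values, dtype=float)
    if X.shape[0] <= X.shape[1]:
        warnings.warn(
            f"only {X.shape[0]} strides for {X.shape[1]} features; "
            "posterior will be prior-dominated", stacklevel=2,
        )
    prior_config = prior_config or {}
    model = ConjugateLinearModel(**prior_config).fit(
        X, y, feature_names=list(FEATURE_NAMES)[: X.shape[1]]
    )
    return PosteriorModel(
        target=target,
        model=model,
        feature_names=tuple(model.feature_names),
        n_train=X.shape[0],
        seed=seed,
    )


def predict(model: PosteriorModel, features, level: float = 0.9) -> pd.DataFrame:
    """Posterior-predictive mean and central credible interval per stride."""
    if isinstance(features, pd.DataFrame):
        ids = features["stride_id"].to_numpy() if "stride_id" in features else None
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        ids = None
        X = np.asarray(features, dtype=float)
    mean, lo, hi = model.model.predict(X, level=level)
    out = pd.DataFrame(
        {
            "posterior_mean": mean,
            "ci_lo": lo,
            "ci_hi": hi,
            "level": level,
            "target": model.target,
        }
    )
    if ids is not None:
        out.insert(0, "stride_id", ids)
    return out


def validate(model: PosteriorModel, features, actuals, level: float = 0.9) -> dict:
    """Held-out calibration: interval coverage, mean error, RMSE."""
    preds = predict(model, features, level=level)
    y = np.asarray(actuals, dtype=float)
    if len(y) == 0:
        raise DomainError("need at least one held-out stride")
    err = preds["posterior_mean"].to_numpy() - y
    covered = (y >= preds["ci_lo"].to_numpy()) & (y <= preds["ci_hi"].to_numpy())
    return {
        "target": model.target,
        "n": len(y),
        "coverage": float(covered.mean()),
        "mean_error": float(err.mean()),
        "rmse": float(np.sqrt((err**2).mean())),
        "level": level,
    }


def compare_predictions(predictions: pd.DataFrame, actuals, group_labels) -> pd.DataFrame:
    """Per-group summary of predicted-minus-actual differences.

    ``predictions`` must carry ``stride_id`` and ``posterior_mean``;
    ``actuals`` and ``group_labels`` are aligned mappings (Series indexed by
    stride_id).  Reports per group the mean difference, a normal-theory 95%
    interval on it, and the fractions of strides with positive/negative
    difference (over-/under-prediction).
    """
    actuals = pd.Series(actuals)
    group_labels = pd.Series(group_labels)
    missing = [s for s in predictions["stride_id"] if s not in actuals.index]
    if missing:
        raise DomainError(f"no actual value for stride(s) {missing[:3]}...")
    diffs = (
        predictions.set_index("stride_id")["posterior_mean"]
        - actuals[predictions["stride_id"]]
    )
    rows = []
    for grp in sorted(group_labels.unique()):
        d = diffs[group_labels[diffs.index] == grp].to_numpy()
        if len(d) == 0:
            continue
        se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else np.nan
        rows.append(
            {
                "group": grp,
                "n": len(d),
                "mean_diff": float(d.mean()),
                "ci_lo": float(d.mean() - 1.96 * se) if len(d) > 1 else np.nan,
                "ci_hi": float(d.mean() + 1.96 * se) if len(d) > 1 else np.nan,
                "frac_positive": float((d > 0).mean()),
                "frac_negative": float((d < 0).mean()),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------- stall experiment

def age_stall_experiment(cohort_config, seed: int, level: float = 0.9) -> dict:
    """Train an age model on AGA strides, predict SGA ages, count underestimates.

    The passed config should describe a cross-sectional cohort; a
    behavioural stall is whatever the config's ``sga_stall_age`` says
    (None disables it).  Reports the fraction of SGA strides with actual
    age beyond the stall boundary (4 h when unset) whose age is
    underestimated, and the mean underestimate among them.
    """
    from .cohort import generate_cohort
    from .normalization import normalize_stride_table

    data = generate_cohort(cohort_config, seed)
    norm = normalize_stride_table(data.strides, g=cohort_config.gravity)
    feats, pca = None, None

    aga = norm[norm["category"] == "AGA"]
    sga = norm[norm["category"] == "SGA"]
    feats_aga, pca = build_feature_table(aga, data.joint_traces, data.piglets)
    feats_sga, _ = build_feature_table(sga, data.joint_traces, data.piglets, pca=pca)

    model = train(feats_aga, feats_aga["actual_age"], target="age", seed=seed)
    preds = predict(model, feats_sga, level=level)
    actual = feats_sga.set_index("stride_id")["actual_age"]

    boundary = cohort_config.sga_stall_age if cohort_config.sga_stall_age else 4.0
    sel = actual[actual > boundary]
    if len(sel) == 0:
        raise DomainError("no SGA strides beyond the stall boundary")
    pred_sel = preds.set_index("stride_id").loc[sel.index, "posterior_mean"]
    under = pred_sel < sel
    return {
        "fraction_underestimated": float(under.mean()),
        "mean_underestimate_h": float((sel - pred_sel)[under].mean()) if under.any() else 0.0,
        "n": int(len(sel)),
        "boundary_h": float(boundary),
    }
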