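"""Data-driven estimation of the trimming parameters epsilon and delta.

The trimming parameters govern how aggressively the precursor (DMS) and
fragment (FMS) mass lists are thinned.  They are estimated by ordinary
least squares on bootstrap-resampled groups of training proteins, with
the coefficients averaged across replicates:

* epsilon is regressed on the cysteine-containing-peptide mass range
  (CCP_max, CCP_min), the CCP count k and the CCP average mass;
* delta on the residue-mass extremes (AA_max, AA_min, AA_average) and
  the average fragment length ||p||.

The regression machinery is generic; user-supplied coefficients can be
loaded from JSON.  When no model or coefficients are configured the
conservative default epsilon = delta = 0.01 applies, further capped in
the pipeline so that the trimming granularity near the target mass stays
below the match window (see io_sim).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .masschem import Peptide, ResidueMassTable, default_table

#: Conservative fallback when no regression model is configured.
DEFAULT_EPSILON = 0.01
DEFAULT_DELTA = 0.01

_CLIP = (1e-6, 0.5)

EPSILON_FEATURE_NAMES = ("ccp_max", "ccp_min", "k", "ccp_average")
DELTA_FEATURE_NAMES = ("aa_max", "aa_min", "aa_average", "avg_fragment_len")


@dataclass(frozen=True)
class EpsilonFeatures:
    ccp_max: float
    ccp_min: float
    k: int
    ccp_average: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ccp_max": self.ccp_max,
            "ccp_min": self.ccp_min,
            "k": float(self.k),
            "ccp_average": self.ccp_average,
        }


@dataclass(frozen=True)
class DeltaFeatures:
    aa_max: float
    aa_min: float
    aa_average: float
    avg_fragment_len: float

    def as_dict(self) -> dict[str, float]:
        return {
            "aa_max": self.aa_max,
            "aa_min": self.aa_min,
            "aa_average": self.aa_average,
            "avg_fragment_len": self.avg_fragment_len,
        }


def epsilon_features(ccp: Sequence[Peptide]) -> EpsilonFeatures:
    """Mass range, count and average mass of the CCP list."""
    if not ccp:
        raise ValueError("empty CCP list")
    masses = [p.mass for p in ccp]
    return EpsilonFeatures(
        ccp_max=max(masses),
        ccp_min=min(masses),
        k=len(masses),
        ccp_average=sum(masses) / len(masses),
    )


def delta_features(
    avg_fragment_len: float, table: ResidueMassTable | None = None
) -> DeltaFeatures:
    table = table or default_table()
    return DeltaFeatures(
        aa_max=table.aa_max,
        aa_min=table.aa_min,
        aa_average=table.aa_average,
        avg_fragment_len=avg_fragment_len,
    )


@dataclass(frozen=True)
class RegressionModel:
    """Affine model: parameter = intercept + coefficients . features."""

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    metadata: dict = field(default_factory=dict)

    def predict(self, features) -> float:
        feats = features.as_dict() if hasattr(features, "as_dict") else dict(features)
        missing = set(self.feature_names) - set(feats)
        if missing:
            raise ValueError(f"features missing for prediction: {sorted(missing)}")
        value = self.intercept + sum(
            c * feats[name] for name, c in zip(self.feature_names, self.coefficients)
        )
        return float(np.clip(value, *_CLIP))

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            coefficients=tuple(payload["coefficients"]),
            intercept=float(payload["intercept"]),
            metadata=payload.get("metadata", {}),
        )


def fit_parameter_model(
    training: Sequence[tuple[object, float]],
    groups_of: int = 4,
    n_boot: int = 200,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> RegressionModel:
    """OLS on bootstrap-resampled groups, coefficients averaged.

    Each replicate draws ``groups_of`` training rows without
    replacement and fits ordinary least squares (minimum-norm when the
    draw is underdetermined); the replicate coefficient vectors are
    averaged.  Deterministic for a fixed seed.
    """
    if len(training) < 2:
        raise ValueError("need at least two training rows")
    if groups_of > len(training):
        raise ValueError("groups_of exceeds the number of training rows")
    feats0 = training[0][0]
    if feature_names is None:
        feats0 = feats0.as_dict() if hasattr(feats0, "as_dict") else dict(feats0)
        feature_names = tuple(sorted(feats0))
    else:
        feature_names = tuple(feature_names)
    rows = []
    y = []
    for features, target in training:
        feats = features.as_dict() if hasattr(features, "as_dict") else dict(features)
        rows.append([feats[name] for name in feature_names])
        y.append(target)
    design = np.column_stack([np.ones(len(rows)), np.array(rows, dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient design: training rows do not span the feature space"
        )
    target = np.array(y, dtype=float)
    rng = np.random.default_rng(seed)
    coefs = np.zeros(design.shape[1])
    for _ in range(n_boot):
        pick = rng.choice(len(rows), size=groups_of, replace=False)
        beta, *_ = np.linalg.lstsq(design[pick], target[pick], rcond=None)
        coefs += beta
    coefs /= n_boot
    return RegressionModel(
        feature_names=feature_names,
        coefficients=tuple(coefs[1:]),
        intercept=float(coefs[0]),
        metadata={"groups_of": groups_of, "n_boot": n_boot, "seed": seed},
    )


def predict_epsilon(model: RegressionModel, features: EpsilonFeatures) -> float:
    return model.predict(features)


def predict_delta(model: RegressionModel, features: DeltaFeatures) -> float:
    return model.predict(features)


#: Single-point calibration fixture: the published worked example pins
#: epsilon = 0.02530 for the ST8Sia IV C142-C292 search (CCP mass range
#: 716..2822, k = 29).  The constant model reproduces that operating
#: point; it is a stored calibration, not a fitted relationship.
ST8SIA4_EPSILON_MODEL = RegressionModel(
    feature_names=EPSILON_FEATURE_NAMES,
    coefficients=(0.0, 0.0, 0.0, 0.0),
    intercept=0.02530,
    metadata={"calibration": "ST8Sia IV C142-C292 worked example"},
)
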