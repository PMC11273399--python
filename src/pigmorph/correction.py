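"""Camera-to-back distance and the learned feature-correction stage.

A bent spine shortens the projected body length, so the raw pixel proxies
``PBL``/``PHW`` are biased.  The fix is supervised: boosted-tree regressors
map per-frame image features to the pig's measured body length and hip
width (cm), and to the camera-to-back distance

    Hdep = Hg - (Hb + Hh) / 2

computed from the camera height ``Hg`` and the measured body and hip
heights.  The corrected triple (BL_hat, HW_hat, Hdep_hat) replaces the raw
pixel features in the later regression strategies.

Split hygiene: the correction model must be fitted on training frames only;
corrected features for held-out frames come from that fitted model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd

from .models import GradientBoosting
from .synthetic import CameraConfig

#: Image features used as correction inputs.  ``Hdep`` itself is a training
#: target, not an input: at inference time only image features exist.  Set
#: ``include_hdep_input=True`` to reproduce the literal protocol for frames
#: whose measured heights are available.
DEFAULT_INPUTS = ("pbl_px", "phw_px", "dev")

TARGETS = ("bl_cm", "hw_cm", "hdep_cm")


def hdep_actual(hg: float, hb: float, hh: float) -> float:
    """Camera-to-back distance (cm) from camera height and body measurements."""
    hdep = hg - (hb + hh) / 2.0
    if hdep <= 0:
        raise ValueError(
            f"camera height {hg} cm is not above the pig's back "
            f"((Hb + Hh)/2 = {(hb + hh) / 2.0} cm)"
        )
    return hdep


@dataclass(frozen=True)
class CorrectedFeatures:
    """Per-frame corrected body length, hip width and camera distance (cm)."""

    bl_hat: float
    hw_hat: float
    hdep_hat: float


class CorrectionModel:
    """Three boosted-tree regressors: image features -> (BL, HW, Hdep) in cm."""

    def __init__(
        self,
        input_features: tuple[str, ...] = DEFAULT_INPUTS,
        hyperparams: dict | None = None,
        seed: int = 0,
    ):
        self.input_features = tuple(input_features)
        self.hyperparams = dict(hyperparams or {})
        self.seed = seed
        self.models_: dict[str, GradientBoosting] = {}

    def _new_model(self, seed: int) -> GradientBoosting:
        hp = self.hyperparams
        return GradientBoosting(
            rounds=hp.get("rounds", 300),
            eta=hp.get("eta", 0.1),
            lam=hp.get("lam", 1.0),
            gamma=hp.get("gamma", 0.0),
            max_depth=hp.get("max_depth", 4),
            seed=seed,
        )

    def fit(self, X: pd.DataFrame, targets: pd.DataFrame) -> "CorrectionModel":
        Xm = X.loc[:, list(self.input_features)].to_numpy(dtype=float)
        self.models_ = {}
        for i, name in enumerate(TARGETS):
            m = self._new_model(seed=self.seed + i)
            m.fit(Xm, targets[name].to_numpy(dtype=float))
            self.models_[name] = m
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.models_:
            raise RuntimeError("correction model is not fitted")
        missing = [c for c in self.input_features if c not in X.columns]
        if missing:
            raise ValueError(f"feature table lacks correction inputs: {missing}")
        Xm = X.loc[:, list(self.input_features)].to_numpy(dtype=float)
        out = {name: self.models_[name].predict(Xm) for name in TARGETS}
        df = pd.DataFrame(
            {
                "bl_hat_cm": out["bl_cm"],
                "hw_hat_cm": out["hw_cm"],
                "hdep_hat_cm": out["hdep_cm"],
            },
            index=X.index,
        )
        if (df[["bl_hat_cm", "hw_hat_cm", "hdep_hat_cm"]] <= 0).any().any():
            warnings.warn("correction produced non-positive body measurements")
        if (df["bl_hat_cm"] <= df["hw_hat_cm"]).any():
            warnings.warn(
                "corrected body length <= hip width for some frames "
                "(implausible posture or poor fit)"
            )
        return df

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "correction",
            "input_features": list(self.input_features),
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "models": {k: m.to_dict() for k, m in self.models_.items()},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @staticmethod
    def from_dict(d: dict) -> "CorrectionModel":
        m = CorrectionModel(
            input_features=tuple(d["input_features"]),
            hyperparams=d["hyperparams"],
            seed=d["seed"],
        )
        m.models_ = {k: GradientBoosting.from_dict(v) for k, v in d["models"].items()}
        return m

    @staticmethod
    def load(path: str) -> "CorrectionModel":
        with open(path) as fh:
            return CorrectionModel.from_dict(json.load(fh))


def correction_frame(
    features: pd.DataFrame,
    biometry: pd.DataFrame,
    camera: CameraConfig,
    include_hdep_input: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-frame features with per-pig targets.

    Returns ``(inputs, targets)`` aligned row-for-row; raises with the list
    of orphan frames when a frame's pig has no biometry row.
    """
    bio = biometry.set_index("pig_id")
    orphans = sorted(set(features["pig_id"]) - set(bio.index))
    if orphans:
        raise ValueError(f"frames reference pigs with no biometry: {orphans}")
    pigs = features["pig_id"]
    targets = pd.DataFrame(
        {
            "bl_cm": bio.loc[pigs, "body_length_cm"].to_numpy(),
            "hw_cm": bio.loc[pigs, "hip_width_cm"].to_numpy(),
            "hdep_cm": [
                hdep_actual(
                    camera.height_above_ground,
                    bio.at[p, "body_height_cm"],
                    bio.at[p, "hip_height_cm"],
                )
                for p in pigs
            ],
        },
        index=features.index,
    )
    inputs = features.copy()
    if include_hdep_input:
        inputs = inputs.assign(hdep_cm=targets["hdep_cm"])
    return inputs, targets


def fit_correction(
    features: pd.DataFrame,
    biometry: pd.DataFrame,
    camera: CameraConfig | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
    include_hdep_input: bool = False,
) -> CorrectionModel:
    """Train the correction stage on (training-split) frames.

    ``features`` needs columns ``pig_id, pbl_px, phw_px, dev``; ``biometry``
    is the per-pig measurement table.  Requires at least two distinct pigs.
    """
    camera = camera or CameraConfig()
    if features["pig_id"].nunique() < 2:
        raise ValueError("correction training needs >= 2 distinct pigs")
    inputs, targets = correction_frame(
        features, biometry, camera, include_hdep_input
    )
    cols = DEFAULT_INPUTS + (("hdep_cm",) if include_hdep_input else ())
    model = CorrectionModel(input_features=cols, hyperparams=hyperparams, seed=seed)
    return model.fit(inputs, targets)


def apply_correction(model: CorrectionModel, features: pd.DataFrame) -> pd.DataFrame:
    """Corrected (bl_hat_cm, hw_hat_cm, hdep_hat_cm) per frame."""
    return model.predict(features)
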