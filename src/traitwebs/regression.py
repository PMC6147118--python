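"""Linear trait-imputation models.

Proboscis length (PL) is predicted from intertegular distance (ITD) with a
single regression pooled across bee species; nectar holder depth (NHD) is
predicted from floral display size (FDS) with one regression per plant
species.  Plant species flagged as having immeasurably shallow nectar
holders receive a fixed 1 mm NHD instead of a model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from traitwebs.data import CommunityDataset, InteractionRecord, SpecimenMeasurement

__all__ = [
    "NHD_FLOOR_MM",
    "PREDICTION_FLOOR_MM",
    "TraitModel",
    "PredictedTraits",
    "fit_trait_model",
    "fit_bee_model",
    "fit_plant_models",
    "predict_nhd",
    "predict_proboscis",
    "predict_traits",
    "summarize_fits",
    "models_to_json",
    "models_from_json",
]

#: NHD assigned to species whose nectar holders are too shallow to measure.
NHD_FLOOR_MM = 1.0
#: Lower clamp for regression predictions (negative-extrapolation guard).
PREDICTION_FLOOR_MM = 0.1


@dataclass(frozen=True)
class TraitModel:
    """An ordinary-least-squares linear trait relation in mm."""

    side: str  # "bee" or "plant"
    species: str  # taxon label or "pooled"
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate_response: bool = False  # SS_tot == 0; r_squared forced to 0

    def predict(self, predictor_mm: float) -> float:
        """Predict the response, clamped below at ``PREDICTION_FLOOR_MM``."""
        value = self.slope * predictor_mm + self.intercept
        if value < PREDICTION_FLOOR_MM:
            warnings.warn(
                f"{self.side} model {self.species!r}: prediction {value:.3g} mm "
                f"clamped to {PREDICTION_FLOOR_MM} mm",
                stacklevel=2,
            )
            return PREDICTION_FLOOR_MM
        return value


@dataclass
class PredictedTraits:
    """Per-record functional sizes: record_id -> (nhd, itd, proboscis, source)."""

    nhd_mm: dict[str, float] = field(default_factory=dict)
    itd_mm: dict[str, float] = field(default_factory=dict)
    proboscis_mm: dict[str, float] = field(default_factory=dict)
    nhd_source: dict[str, str] = field(default_factory=dict)  # "regression"|"floor"


def fit_trait_model(
    points: Sequence[tuple[float, float]],
    side: str,
    species: str,
) -> TraitModel:
    """Fit response = slope * predictor + intercept by OLS.

    Requires at least two points and a non-constant predictor.  A constant
    response gives slope 0 and r_squared 0 (flagged, with a warning) since
    SS_tot vanishes.
    """
    if len(points) < 2:
        raise ValueError(f"{side}/{species}: need >=2 points, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"{side}/{species}: degenerate regression (constant predictor)")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = float(sxy / sxx)
    intercept = float(ym - slope * xm)
    ss_tot = float(np.sum((y - ym) ** 2))
    degenerate = ss_tot == 0.0
    if degenerate:
        warnings.warn(
            f"{side}/{species}: constant response, r_squared reported as 0",
            stacklevel=2,
        )
        r2 = 0.0
    else:
        ss_res = float(np.sum((y - slope * x - intercept) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    return TraitModel(
        side=side,
        species=species,
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_points=len(points),
        degenerate_response=degenerate,
    )


def fit_bee_model(specimens: Iterable[SpecimenMeasurement]) -> TraitModel:
    """Pooled PL-from-ITD regression over all bee specimens."""
    points = [(s.predictor_mm, s.response_mm) for s in specimens if s.side == "bee"]
    return fit_trait_model(points, side="bee", species="pooled")


def fit_plant_models(
    specimens: Iterable[SpecimenMeasurement],
    floors: set[str] | frozenset[str] = frozenset(),
) -> dict[str, TraitModel]:
    """Per-species NHD-from-FDS regressions; floor species get no model."""
    by_species: dict[str, list[tuple[float, float]]] = {}
    for s in specimens:
        if s.side == "plant" and s.species not in floors:
            by_species.setdefault(s.species, []).append((s.predictor_mm, s.response_mm))
    return {
        sp: fit_trait_model(pts, side="plant", species=sp)
        for sp, pts in sorted(by_species.items())
    }


def predict_nhd(
    models: Mapping[str, TraitModel],
    floors: set[str] | frozenset[str],
    record: InteractionRecord,
) -> tuple[float, str]:
    """Nectar holder depth for one record: (value_mm, "regression"|"floor")."""
    if record.plant_species in floors:
        return NHD_FLOOR_MM, "floor"
    model = models.get(record.plant_species)
    if model is None:
        raise KeyError(
            f"plant species {record.plant_species!r} has neither a trait model "
            "nor an immeasurable (floor) flag"
        )
    return model.predict(record.fds_mm), "regression"


def predict_proboscis(model: TraitModel, itd_mm: float) -> float:
    """Proboscis length from ITD via the pooled bee model."""
    return model.predict(itd_mm)


def predict_traits(
    ds: CommunityDataset,
    bee_model: TraitModel | None = None,
    plant_models: Mapping[str, TraitModel] | None = None,
) -> PredictedTraits:
    """Impute functional sizes for every interaction record in a dataset."""
    if bee_model is None:
        bee_model = fit_bee_model(ds.specimens)
    if plant_models is None:
        plant_models = fit_plant_models(ds.specimens, ds.immeasurable_plant_species)
    out = PredictedTraits()
    for rec in ds.interactions:
        nhd, source = predict_nhd(plant_models, ds.immeasurable_plant_species, rec)
        out.nhd_mm[rec.record_id] = nhd
        out.nhd_source[rec.record_id] = source
        out.itd_mm[rec.record_id] = rec.itd_mm
        out.proboscis_mm[rec.record_id] = predict_proboscis(bee_model, rec.itd_mm)
    return out


def summarize_fits(models: Sequence[TraitModel]) -> tuple[float, float, int]:
    """Mean and sample SD of r_squared over models; SD is 0 for one model."""
    if not models:
        raise ValueError("summarize_fits: empty model list")
    r2 = np.array([m.r_squared for m in models], dtype=float)
    if len(r2) == 1:
        warnings.warn("single model: SD undefined, reported as 0", stacklevel=2)
        return float(r2[0]), 0.0, 1
    return float(r2.mean()), float(r2.std(ddof=1)), len(r2)


def models_to_json(models: Iterable[TraitModel], path: str | Path) -> None:
    payload = [
        {
            "side": m.side,
            "species": m.species,
            "slope": m.slope,
            "intercept": m.intercept,
            "r_squared": m.r_squared,
            "n_points": m.n_points,
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def models_from_json(path: str | Path) -> list[TraitModel]:
    payload = json.loads(Path(path).read_text())
    return [TraitModel(**entry) for entry in payload]
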