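"""Per-target potency regression and dual-target candidate prioritization.

Compounds are featurized as binary circular (Morgan) fingerprints and a
gradient-boosted tree ensemble is fitted per target on an 80/20
train/test split.  Virtual candidates from expanded SAR matrices are
then ranked by their worst per-target predicted-potency rank, so that
only compounds predicted potent against *both* targets lead the list.
Predicted values are relative: models trained on actives only place all
predictions inside the training potency range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from .errors import ContractError, ParseError
from .sarm_core import Sarm, enumerate_virtual_cells

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FingerprintSpec:
    radius: int = 2
    n_bits: int = 1024


def featurize(compounds: list[str], spec: FingerprintSpec | None = None) -> np.ndarray:
    """Binary Morgan fingerprint matrix, one row per compound (order kept)."""
    spec = spec or FingerprintSpec()
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.radius, fpSize=spec.n_bits
    )
    rows = np.zeros((len(compounds), spec.n_bits), dtype=np.uint8)
    for n, smi in enumerate(compounds):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ParseError(f"row {n}: unparsable SMILES {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows[n, list(fp.GetOnBits())] = 1
    return rows


@dataclass
class PotencyModel:
    target: str
    featurization: FingerprintSpec
    model: LGBMRegressor
    split_seed: int
    r2_train: float
    r2_test: float
    train_range: tuple[float, float]
    fitted: bool = True


#: desk-scale GBDT settings for data sets of hundreds of compounds
GBDT_PARAMS = dict(
    n_estimators=500,
    learning_rate=0.05,
    num_leaves=31,
    min_child_samples=5,
    n_jobs=1,
    deterministic=True,
    force_row_wise=True,
    verbose=-1,
)


def train_potency_model(
    features: np.ndarray,
    potencies: np.ndarray,
    target: str = "",
    split_fraction: float = 0.8,
    seed: int = 0,
    featurization: FingerprintSpec | None = None,
    measurement_types: list[str] | None = None,
) -> PotencyModel:
    """Fit a gradient-boosted regressor on a train/test split.

    ``measurement_types`` (e.g. IC50 vs Ki per compound) must be
    homogeneous: mixed measurement types are not comparable on one pIC50
    scale and are rejected.  R^2 on both split halves is recorded at fit
    time; the same seed always reproduces the same split and fit.
    """
    potencies = np.asarray(potencies, dtype=float)
    if len(features) != len(potencies):
        raise ContractError("features and potencies differ in length")
    if len(potencies) < 25:
        raise ContractError(f"need >= 25 compounds to fit, got {len(potencies)}")
    if measurement_types is not None and len(set(measurement_types)) > 1:
        raise ContractError(
            f"mixed measurement types {sorted(set(measurement_types))}: "
            "IC50 and Ki values cannot be compared on one scale"
        )
    if np.ptp(potencies) == 0:
        raise ContractError("constant potency vector: R^2 is undefined")
    x_train, x_test, y_train, y_test = train_test_split(
        _named_bits(features), potencies, train_size=split_fraction,
        random_state=seed,
    )
    booster = LGBMRegressor(random_state=seed, **GBDT_PARAMS)
    booster.fit(x_train, y_train)
    model = PotencyModel(
        target=target,
        featurization=featurization or FingerprintSpec(),
        model=booster,
        split_seed=seed,
        r2_train=float(r2_score(y_train, booster.predict(x_train))),
        r2_test=float(r2_score(y_test, booster.predict(x_test))),
        train_range=(float(potencies.min()), float(potencies.max())),
    )
    logger.info(
        "model[%s]: n=%d, R2 train %.3f / test %.3f",
        target, len(potencies), model.r2_train, model.r2_test,
    )
    return model


def predict_potency(model: PotencyModel, compounds: list[str]) -> np.ndarray:
    """Predict pIC50 for compounds given as SMILES.

    Predictions are relative: a model trained on actives only predicts
    inside (a small margin around) the training potency range.
    """
    if not getattr(model, "fitted", False):
        raise ContractError("model is not fitted")
    if not compounds:
        return np.empty(0)
    logger.info(
        "predictions for %d compounds are on a relative scale "
        "(training range %.2f..%.2f)", len(compounds), *model.train_range
    )
    bits = _named_bits(featurize(compounds, model.featurization))
    return np.asarray(model.model.predict(bits))


def _named_bits(features: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(features, columns=[f"bit{i}" for i in range(features.shape[1])])


@dataclass(frozen=True)
class DualPrediction:
    smiles: str
    predicted: dict[str, float] = field(hash=False)
    per_target_rank: dict[str, int] = field(hash=False)
    combined_rank: int = 0
    ll_score: float | None = None


def prioritize_dual(
    sarm: Sarm,
    model_a: PotencyModel,
    model_b: PotencyModel,
    top_n: int,
    rank_mode: str = "worst",
) -> list[DualPrediction]:
    """Rank the matrix's virtual candidates for dual-target potential.

    Per-target ranks (1 = highest predicted pIC50) are combined by the
    worst (largest) of the two — the best worst-case, so a candidate must
    score well against both targets to lead.  ``rank_mode="mean"`` uses
    the mean rank instead.  Ties break by mean predicted potency, then by
    generator log-likelihood score, then SMILES.
    """
    if rank_mode not in ("worst", "mean"):
        raise ContractError(f"unknown rank_mode {rank_mode!r}")
    if top_n <= 0:
        return []
    cells = enumerate_virtual_cells(sarm)
    if not cells:
        return []
    smiles = [c.smiles for c in cells]
    pred_a = predict_potency(model_a, smiles)
    pred_b = predict_potency(model_b, smiles)
    rank_a = _dense_rank(-pred_a)
    rank_b = _dense_rank(-pred_b)
    combine = np.maximum if rank_mode == "worst" else lambda a, b: (a + b) / 2.0
    combined = combine(rank_a, rank_b)
    order = sorted(
        range(len(cells)),
        key=lambda n: (
            combined[n],
            -(pred_a[n] + pred_b[n]) / 2.0,
            -(cells[n].ll_score if cells[n].ll_score is not None else 0.0),
            smiles[n],
        ),
    )
    name_a = model_a.target or "A"
    name_b = model_b.target or "B"
    return [
        DualPrediction(
            smiles=smiles[n],
            predicted={name_a: float(pred_a[n]), name_b: float(pred_b[n])},
            per_target_rank={name_a: int(rank_a[n]), name_b: int(rank_b[n])},
            combined_rank=pos + 1,
            ll_score=cells[n].ll_score,
        )
        for pos, n in enumerate(order[:top_n])
    ]


def _dense_rank(values: np.ndarray) -> np.ndarray:
    """1-based ranks, ascending, ties sharing a rank."""
    uniq = np.unique(values)
    return np.searchsorted(uniq, values) + 1
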