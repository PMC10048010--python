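"""Shape PCA and assembly of the predictor table.

After superimposition each specimen is a point in shape space (the flattened
aligned coordinates).  A covariance-matrix PCA per tooth reduces these to the
leading components; the per-tooth PC scores plus the natural logarithm of
each tooth's centroid size form the predictor table for the classifier — for
three teeth and 30 components per tooth, 93 predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingToothError, SchemaError
from .procrustes import AlignedSample
from .types import Tooth


@dataclass
class ShapePca:
    """Principal components of one tooth's aligned shape coordinates.

    ``components`` (k, 3n) are orthonormal; eigenvalues are the score
    variances (descending).  The sign convention makes each component's
    largest-magnitude loading positive, so results are deterministic.
    """

    tooth: Tooth
    mean_vector: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    total_variance: float
    specimen_ids: list

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def transform(self, flattened: np.ndarray) -> np.ndarray:
        """Project (possibly new) flattened shape coordinates onto the
        retained components."""
        x = np.atleast_2d(np.asarray(flattened, dtype=float))
        if x.shape[1] != self.mean_vector.shape[0]:
            raise InvalidInputError(
                f"expected {self.mean_vector.shape[0]} coordinates, got {x.shape[1]}"
            )
        return (x - self.mean_vector) @ self.components.T

    def to_json(self) -> str:
        return json.dumps(
            {
                "tooth": self.tooth.value,
                "mean_vector": self.mean_vector.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "components": self.components.tolist(),
                "total_variance": self.total_variance,
            }
        )


def shape_pca(aligned: AlignedSample, n_components: int = 30) -> ShapePca:
    """PCA of the covariance matrix of aligned shape coordinates.

    Centers the flattened coordinates, eigendecomposes their covariance (via
    SVD of the centered matrix) and retains the leading ``n_components``.
    """
    x = aligned.flattened()
    n = x.shape[0]
    if n < 2:
        raise InvalidInputError("PCA needs at least two specimens")
    max_k = min(n - 1, x.shape[1])
    if not 1 <= n_components <= max_k:
        raise InvalidInputError(
            f"n_components must be in [1, {max_k}] for {n} specimens "
            f"and {x.shape[1]} coordinates, got {n_components}"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total_variance = float(np.sum(xc**2) / (n - 1))
    comps = vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    scores = xc @ comps.T
    return ShapePca(
        tooth=aligned.tooth,
        mean_vector=mean,
        eigenvalues=eigenvalues[:n_components],
        components=comps,
        scores=scores,
        variance_fractions=eigenvalues[:n_components] / total_variance,
        total_variance=total_variance,
        specimen_ids=list(aligned.specimen_ids),
    )


@dataclass
class PredictorTable:
    """Per-specimen predictor matrix with optional sex labels."""

    table: pd.DataFrame
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise SchemaError("predictor table contains missing cells")
        if self.table.columns.duplicated().any():
            raise SchemaError("duplicate predictor column names")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.table.index)
            if self.labels.isna().any():
                missing = list(self.table.index[self.labels.isna()])
                raise SchemaError(f"missing sex labels for {missing}")

    @property
    def n_predictors(self) -> int:
        return self.table.shape[1]

    @property
    def specimen_ids(self) -> list:
        return list(self.table.index)

    def matrix(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    def standardized(self, mean=None, sd=None) -> "PredictorTable":
        """Center/scale columns; pass training-set mean/sd to transform a
        held-out partition without leakage."""
        mean = self.table.mean() if mean is None else mean
        sd = self.table.std(ddof=1) if sd is None else sd
        sd = sd.replace(0.0, 1.0)
        return PredictorTable((self.table - mean) / sd, self.labels)


def predictor_names(tooth: Tooth, n_components: int) -> list:
    t = Tooth(tooth).value
    return [f"{t}{i + 1:03d}" for i in range(n_components)] + [f"{t}_lnCS"]


def assemble_predictors(
    pcas: Mapping[Tooth, ShapePca],
    aligned: Mapping[Tooth, AlignedSample],
    labels: Optional[Mapping[str, str]] = None,
    specimen_ids: Optional[Sequence[str]] = None,
) -> PredictorTable:
    """Concatenate per-tooth PC scores and log centroid sizes.

    For each tooth: ``n_components`` PC scores (columns FP001...) plus
    ln(centroid size) (column FP_lnCS).  Three teeth at 30 components give
    exactly 93 predictors.  Every specimen must be present for every tooth.
    """
    if not pcas:
        raise InvalidInputError("no PCA models given")
    teeth = [Tooth(t) for t in pcas]
    base_ids = list(specimen_ids) if specimen_ids is not None else list(
        aligned[teeth[0]].specimen_ids
    )
    blocks = []
    for tooth in teeth:
        sample = aligned[tooth]
        ids = list(sample.specimen_ids)
        missing = [s for s in base_ids if s not in set(ids)]
        extra = [s for s in ids if s not in set(base_ids)]
        if missing or extra:
            raise MissingToothError(
                f"tooth {tooth.value}: specimens missing={missing} extra={extra}"
            )
        order = [ids.index(s) for s in base_ids]
        pca = pcas[tooth]
        scores = pca.transform(sample.flattened()[order])
        ln_cs = np.log(sample.centroid_sizes[order])
        block = pd.DataFrame(
            np.column_stack([scores, ln_cs]),
            index=base_ids,
            columns=predictor_names(tooth, pca.n_components),
        )
        blocks.append(block)
    table = pd.concat(blocks, axis=1)
    lab = None
    if labels is not None:
        lab = pd.Series({s: labels[s] for s in base_ids}, name="sex")
    return PredictorTable(table, lab)
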