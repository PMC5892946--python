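"""Cross-background transfer of mutational transcriptional responses.

The transcriptional response to a mutation set is the replicate-averaged
difference between the final and initial expression states (log2,
quantile-normalized).  Assuming the response is background-independent, a
hypothetical expression state is constructed by adding the response to each
replicate of another deletion background; its growth rate is then predicted
with the eigengene-KNN model and reported as the mean percent change relative
to the background's measured growth rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression_core import ExpressionMatrix
from .eigengene_space import EigengeneBasis, project, transform_profiles
from .knn_growth import KnnGrowthModel, predict_many

__all__ = ["mean_response", "apply_response", "transfer_matrix"]


def mean_response(final: np.ndarray, initial: np.ndarray) -> np.ndarray:
    """Replicate-averaged per-gene response (log2 units).

    ``final`` and ``initial`` are genes x replicates arrays paired by
    replicate index (replicates are day-batched, so pairing by index cancels
    shared batch offsets).  Raises when the replicate counts differ.
    """
    final = np.atleast_2d(np.asarray(final, dtype=float))
    initial = np.atleast_2d(np.asarray(initial, dtype=float))
    if final.shape != initial.shape:
        raise ValueError(
            f"unpaired replicate layout: final {final.shape} vs initial {initial.shape}"
        )
    return (final - initial).mean(axis=1)


def apply_response(background: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Add a response vector to every background replicate.

    Operates on log2(x+1) values; results are floored at zero, the log2
    image of zero linear expression, so no hypothetical state goes below
    zero counts.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    response = np.asarray(response, dtype=float)
    if response.ndim != 1 or response.size != background.shape[0]:
        raise ValueError("response misaligned with background gene axis")
    return np.clip(background + response[:, None], 0.0, None)


def transfer_matrix(
    backgrounds: dict[str, ExpressionMatrix],
    responses: dict[str, np.ndarray],
    model: KnnGrowthModel,
    basis: EigengeneBasis,
    measured_rates: dict[str, float],
    response_source: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Predict every response in every background.

    For each (background, response) pair the response is added to each
    background replicate, the hypothetical profiles are projected onto the
    model's eigengenes, and growth is predicted per replicate.  Reported per
    pair: the mean predicted rate, the mean percent change versus the
    background's measured rate, its standard error over replicates, and a
    ``self_pair`` flag marking responses applied in their source background.

    ``backgrounds`` maps background id to its replicate expression matrix
    (linear scale); ``responses`` maps response id to a log2 response vector
    aligned to the basis gene list; ``response_source`` maps response id to
    the background it was measured in.
    """
    rows = []
    for bg_id, matrix in backgrounds.items():
        transformed = transform_profiles(matrix, basis)
        measured = float(measured_rates[bg_id])
        if measured <= 0:
            raise ValueError(f"measured rate for {bg_id!r} must be positive")
        for resp_id, response in responses.items():
            hypothetical = apply_response(transformed, response)
            coords = project(hypothetical, basis, model.selected_indices).T
            rates = predict_many(coords, model)
            pct = 100.0 * (rates - measured) / measured
            rows.append(
                {
                    "background": bg_id,
                    "response": resp_id,
                    "mean_predicted_rate": float(rates.mean()),
                    "mean_pct_change": float(pct.mean()),
                    "se_pct_change": float(
                        pct.std(ddof=1) / np.sqrt(pct.size) if pct.size > 1 else 0.0
                    ),
                    "n_replicates": int(pct.size),
                    "self_pair": bool(
                        response_source is not None
                        and response_source.get(resp_id) == bg_id
                    ),
                }
            )
    return pd.DataFrame(rows)
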