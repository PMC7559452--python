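"""smORF expression estimation from probe-set signals.

Probe-set signals are RMA-level: background-corrected, normalised, log2
scale. Because the log2 was already taken, attribution of shared probe-set
signal to a smORF happens on the linear scale: for the n probe sets annotated
to a smORF with weights w_1..w_n and per-sample signals RMA_1..RMA_n,

    E = log2( estimator( w_1 * 2^RMA_1, ..., w_n * 2^RMA_n ) ),  w_i > 0.1

with the median as the default estimator (mean and max are provided for
comparison). Annotations with w <= 0.1 are discarded; a smORF whose
annotations all fall below the threshold is excluded from the output and
reported, rather than emitted as missing values, so downstream matrices stay
dense.

Scaling all surviving weights of a smORF by c > 0 adds log2 c to E in every
sample, leaving the smORF's per-sample ranks — and hence every downstream
Spearman correlation — unchanged.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .genome import ProbeSetAnnotation

#: Annotation weights at or below this value are ignored (strict w > 0.1).
DEFAULT_WEIGHT_MIN = 0.1

ESTIMATORS = {
    "median": lambda a: np.median(a, axis=0),
    "mean": lambda a: np.mean(a, axis=0),
    "max": lambda a: np.max(a, axis=0),
}


def aggregate_duplicate_features(
    matrix: pd.DataFrame, id_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse rows sharing a canonical id to their per-sample median.

    ``id_map`` must cover every feature in ``matrix`` (e.g. probe set id to
    Entrez gene id). Output rows are sorted by canonical id. The even-count
    median interpolates (mean of the two middle values).
    """
    if matrix.empty:
        return matrix.copy()
    missing = [f for f in matrix.index if f not in id_map]
    if missing:
        raise DataError(
            f"id_map does not cover {len(missing)} features, "
            f"e.g. {missing[:3]}"
        )
    canonical = matrix.index.map(lambda f: id_map[f])
    out = matrix.groupby(canonical).median()
    out.index.name = matrix.index.name
    return out.sort_index()


def estimate_smorf_expression(
    probe_signals: pd.DataFrame,
    annotations: Iterable[ProbeSetAnnotation],
    estimator: str = "median",
    weight_min: float = DEFAULT_WEIGHT_MIN,
) -> tuple[pd.DataFrame, list[str]]:
    """Estimate per-sample smORF expression from weighted probe-set signals.

    Parameters
    ----------
    probe_signals
        Probe sets x samples, log2 scale.
    annotations
        Probe-set -> smORF links with weights; weights <= ``weight_min`` are
        dropped, negative weights abort.
    estimator
        ``median`` (default), ``mean`` or ``max``, applied per sample to the
        weighted linear-scale signals.

    Returns
    -------
    (expression, unquantifiable)
        smORFs x samples log2 expression matrix (rows sorted by smORF id),
        plus the ids of smORFs whose annotations all fell below the weight
        threshold or were absent.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator!r}; expected one of {sorted(ESTIMATORS)}"
        )
    agg = ESTIMATORS[estimator]

    surviving: dict[str, list[ProbeSetAnnotation]] = defaultdict(list)
    all_smorfs: set[str] = set()
    for ann in annotations:
        if ann.weight < 0:
            raise DataError(
                f"negative weight for {ann.probe_set_id}->{ann.smorf_id}"
            )
        all_smorfs.add(ann.smorf_id)
        if ann.weight > weight_min:
            surviving[ann.smorf_id].append(ann)

    rows: dict[str, np.ndarray] = {}
    unquantifiable: list[str] = []
    for smorf_id in sorted(all_smorfs):
        anns = surviving.get(smorf_id)
        if not anns:
            unquantifiable.append(smorf_id)
            continue
        missing = [a.probe_set_id for a in anns if a.probe_set_id not in probe_signals.index]
        if missing:
            raise DataError(
                f"smORF {smorf_id}: probe sets {missing} absent from signal matrix"
            )
        weights = np.array([a.weight for a in anns], dtype=float)
        signals = probe_signals.loc[[a.probe_set_id for a in anns]].to_numpy(dtype=float)
        linear = weights[:, None] * np.exp2(signals)
        rows[smorf_id] = np.log2(agg(linear))

    expr = pd.DataFrame.from_dict(rows, orient="index", columns=probe_signals.columns)
    expr = expr.sort_index()
    expr.index.name = "smorf_id"
    return expr, unquantifiable
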