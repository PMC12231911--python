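"""Signature scoring: mean z-score signature scores, coherence, d_mean.

The mean signature score of a sample is the average, over the signature's
genes found in the matrix, of the across-sample z-scaled log2(x + 1)
expression (so scores of a fully present signature sum to zero across
samples by construction).  The coherence score of a signature in a dataset
is the mean Pearson correlation over all unordered pairs of its usable
genes, gauging whether the set behaves as one transcriptional module.
d_mean is the shift of the mean signature score of a stimulated group
relative to the unstimulated controls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import CONTROL
from .sigdiscovery import GeneSignature

logger = logging.getLogger(__name__)

MISSING_WARN_FRACTION = 0.5


@dataclass
class ScoreTable:
    """samples x signatures score matrix plus per-signature gene bookkeeping."""

    scores: pd.DataFrame
    genes_used: dict[str, list[str]]
    genes_missing: dict[str, list[str]]


@dataclass
class CoherenceReport:
    """Per-signature mean pairwise Pearson correlation (NaN when undefined)."""

    coherence: pd.Series
    n_pairs: pd.Series


def _log_matrix(matrix: pd.DataFrame, already_log: bool) -> pd.DataFrame:
    logm = matrix if already_log else np.log2(matrix + 1.0)
    logm = logm.copy()
    logm.index = logm.index.str.upper()
    return logm


def _present_genes(
    logm: pd.DataFrame, signature: GeneSignature
) -> tuple[list[str], list[str]]:
    wanted = [g.upper() for g in signature.genes]
    index = set(logm.index)
    used = [g for g in wanted if g in index]
    missing = [g for g in wanted if g not in index]
    if missing and len(missing) / len(wanted) > MISSING_WARN_FRACTION:
        logger.warning(
            "signature %s: %d/%d genes missing from the matrix",
            signature.name, len(missing), len(wanted),
        )
    return used, missing


def mean_signature_score(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    already_log: bool = False,
) -> pd.Series:
    """Per-sample mean of across-sample z-scaled log2 expression.

    Zero-variance genes contribute z = 0; missing genes are dropped (with a
    warning above 50% missingness).  Requires >= 2 samples (the z-score is
    undefined for one) and at least one signature gene in the matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scaling needs at least 2 samples")
    logm = _log_matrix(matrix, already_log)
    used, _ = _present_genes(logm, signature)
    if not used:
        raise ValueError(f"no genes of signature {signature.name} in the matrix")
    sub = logm.loc[used]
    sd = sub.std(axis=1, ddof=1)
    centered = sub.sub(sub.mean(axis=1), axis=0)
    z = centered.div(sd.where(sd > 0, np.inf), axis=0)
    return z.mean(axis=0).rename(signature.name)


def score_table(
    matrix: pd.DataFrame,
    signatures: dict[str, GeneSignature] | list[GeneSignature],
    already_log: bool = False,
) -> ScoreTable:
    """Score every signature against the matrix."""
    sigs = list(signatures.values()) if isinstance(signatures, dict) else signatures
    logm = _log_matrix(matrix, already_log)
    columns, used_map, missing_map = {}, {}, {}
    for sig in sigs:
        used, missing = _present_genes(logm, sig)
        used_map[sig.name] = used
        missing_map[sig.name] = missing
        columns[sig.name] = mean_signature_score(matrix, sig, already_log=already_log)
    return ScoreTable(
        scores=pd.DataFrame(columns),
        genes_used=used_map,
        genes_missing=missing_map,
    )


def coherence_score(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    already_log: bool = False,
) -> tuple[float, int]:
    """Mean Pearson correlation over all unordered gene pairs.

    Returns (coherence, number of pairs); (NaN, 0) with a warning when fewer
    than two usable (present, non-constant) genes exist.  Needs >= 3 samples
    for a meaningful correlation.
    """
    if matrix.shape[1] < 3:
        raise ValueError("coherence needs at least 3 samples")
    logm = _log_matrix(matrix, already_log)
    used, _ = _present_genes(logm, signature)
    sub = logm.loc[used]
    usable = sub[sub.std(axis=1, ddof=1) > 0]
    if usable.shape[0] < 2:
        logger.warning(
            "signature %s: fewer than 2 usable genes, coherence undefined",
            signature.name,
        )
        return float("nan"), 0
    corr = np.corrcoef(usable.to_numpy(float))
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean()), len(iu[0])


def coherence_report(
    matrix: pd.DataFrame,
    signatures: dict[str, GeneSignature] | list[GeneSignature],
    already_log: bool = False,
) -> CoherenceReport:
    sigs = list(signatures.values()) if isinstance(signatures, dict) else signatures
    values, pairs = {}, {}
    for sig in sigs:
        values[sig.name], pairs[sig.name] = coherence_score(
            matrix, sig, already_log=already_log
        )
    return CoherenceReport(coherence=pd.Series(values), n_pairs=pd.Series(pairs))


def d_mean(
    scores: pd.Series,
    conditions: pd.Series,
    condition: str | None = None,
) -> float | pd.Series:
    """Mean score shift of a stimulated group relative to the controls.

    With ``condition=None`` returns a Series over every non-control condition
    present.  Raises when the control arm is missing.
    """
    conditions = conditions.loc[scores.index]
    control_scores = scores[conditions == CONTROL]
    if len(control_scores) == 0:
        raise ValueError("no control samples")
    baseline = control_scores.mean()

    def one(cond: str) -> float:
        group = scores[conditions == cond]
        if len(group) == 0:
            raise ValueError(f"no samples with condition {cond!r}")
        return float(group.mean() - baseline)

    if condition is not None:
        return one(condition)
    present = [c for c in pd.unique(conditions) if c != CONTROL]
    return pd.Series({c: one(c) for c in present})
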