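"""File formats: expression matrices (TSV/CSV/MTX triplet), annotation
tables, GMT gene sets and the plain-TSV intermediate artifacts of the
pipeline.  Intermediate tables carry commented header lines recording the
thresholds used, so every filtering step is auditable."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sigdiscovery import GeneSignature

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices and annotations
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Genes x samples matrix from TSV, CSV or an MTX triplet.

    ``fmt`` is inferred from the suffix when omitted ("mtx" expects
    ``<stem>.mtx`` plus ``<stem>.genes.txt`` and ``<stem>.samples.txt``).
    Duplicate gene symbols are collapsed by their mean with a warning;
    non-numeric cells raise with their location.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format of {path}")
    if fmt == "mtx":
        from scipy.io import mmread

        matrix = np.asarray(mmread(path).todense(), dtype=float)
        genes = Path(str(path)[: -len(".mtx")] + ".genes.txt").read_text().split()
        samples = Path(str(path)[: -len(".mtx")] + ".samples.txt").read_text().split()
        frame = pd.DataFrame(matrix, index=genes, columns=samples)
    else:
        sep = "\t" if fmt == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        for col in frame.columns:
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                gene = frame.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
                )
            frame[col] = converted
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        n = int(frame.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene symbols collapsed by mean", path, n)
        frame = frame.groupby(level=0, sort=False).mean()
    return frame


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene")


def read_annotations(path: str | Path, samples: list[str] | None = None) -> pd.DataFrame:
    """Sample annotation TSV (columns: sample, condition, dose, time, ...).

    When ``samples`` is given, every sample must be annotated.
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    if "sample" not in table.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    table = table.set_index("sample")
    if samples is not None:
        missing = [s for s in samples if s not in table.index]
        if missing:
            raise ValueError(f"{path}: samples without annotation: {missing[:5]}")
    return table


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def parse_gmt(lines) -> dict[str, GeneSignature]:
    """Order-preserving GMT parse (name TAB description TAB gene ...)."""
    signatures: dict[str, GeneSignature] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
        name = fields[0]
        genes = tuple(g for g in fields[2:] if g)
        signatures[name] = GeneSignature(name=name, genes=genes, provenance="fixture")
    if not signatures:
        logger.warning("GMT input contained no gene sets")
    return signatures


def read_gmt(path: str | Path) -> dict[str, GeneSignature]:
    with open(path) as handle:
        return parse_gmt(handle)


def write_gmt(
    signatures: dict[str, GeneSignature] | list[GeneSignature], path: str | Path
) -> None:
    sigs = list(signatures.values()) if isinstance(signatures, dict) else signatures
    with open(path, "w") as handle:
        for sig in sigs:
            description = sig.provenance or "na"
            handle.write("\t".join([sig.name, description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# pipeline artifacts
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, header_comments: dict | None = None,
                index: bool = False) -> None:
    """TSV with ``# key: value`` comment lines recording run parameters."""
    with open(path, "w") as handle:
        for key, value in (header_comments or {}).items():
            handle.write(f"# {key}: {value}\n")
        frame.to_csv(handle, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
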