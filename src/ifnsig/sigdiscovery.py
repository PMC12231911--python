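"""Signature derivation from per-gene network meta-analysis results.

The discovery logic mirrors the dual-threshold workflow: six directional
differentially-expressed-gene (DEG) lists from the three treatment-pair
comparisons (|FC| above a cutoff, FDR below a cutoff), three upregulated
lists from the treatment-vs-control comparisons (stricter FC cutoff), and a
union/intersect/subtract step per interferon:

    S_X   = (union over pairwise comparisons of genes up in X)
            intersected with (genes up in X vs control)
    S_b  := S_b minus S_a        (IFN-a genes removed from the IFN-b set)

S_IFNa is reported as the type-I signature and S_IFNg as the type-II
signature.  Fold-change cutoffs are interpreted on the linear scale by
default (a cutoff of 3 means 2^|logFC| > 3); the literal log2 reading is
available via ``effect_scale="log2"``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .dge import CONTROL, TREATMENTS
from .netmeta import NetworkResult

logger = logging.getLogger(__name__)

PAIRWISE_EFFECT_THRESHOLD = 2.5
VS_CONTROL_EFFECT_THRESHOLD = 3.0
FDR_THRESHOLD = 0.05

#: sha256 of the bundled signature GMT (published IFN Aybey gene lists)
_FIXTURE_FILE = "ifn_aybey_signatures.gmt"
_FIXTURE_SHA256 = "02e7f03b5fb4fd38d8aea9d93d173db7df2efeda76a9c9d55a1ed6dfd5490114"


@dataclass(frozen=True)
class GeneSignature:
    """Named ordered set of gene symbols."""

    name: str
    genes: tuple[str, ...]
    provenance: str = "derived"  # "derived" | "fixture"

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"{self.name}: duplicate gene symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class DegList:
    """Directional DEG list for one comparison: genes higher in ``up_in``."""

    a: str
    b: str
    up_in: str
    genes: frozenset[str]
    effect_threshold: float
    fdr_threshold: float
    effect_scale: str


def _passes_effect(effect: float, threshold: float, scale: str) -> bool:
    if scale == "linear":
        return bool(2.0 ** effect > threshold)
    if scale == "log2":
        return bool(effect > threshold)
    raise ValueError(f"unknown effect scale {scale!r}")


def _passes_fdr(q: float, threshold: float, direction: str) -> bool:
    if not np.isfinite(q):
        return False
    if direction == "corrected":
        return bool(q < threshold)
    if direction == "literal":
        return bool(q > threshold)
    raise ValueError(f"unknown fdr direction {direction!r}")


def pairwise_deg_lists(
    results: list[NetworkResult],
    effect_threshold: float = PAIRWISE_EFFECT_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    effect_scale: str = "linear",
    fdr_direction: str = "corrected",
) -> list[DegList]:
    """Six directional lists from the three treatment-pair comparisons.

    A gene joins the list of the condition with the higher estimate when
    |FC| exceeds the cutoff and the comparison's q-value passes; it can never
    sit in both directional lists of a comparison.
    """
    lists = []
    pairs = [(a, b) for i, a in enumerate(TREATMENTS) for b in TREATMENTS[i + 1:]]
    for a, b in pairs:
        for up_in, down_in in ((a, b), (b, a)):
            members = set()
            for r in results:
                eff = r.effect.loc[up_in, down_in]
                q = r.fdr.loc[up_in, down_in]
                if (
                    np.isfinite(eff)
                    and _passes_effect(abs(eff), effect_threshold, effect_scale)
                    and eff > 0
                    and _passes_fdr(q, fdr_threshold, fdr_direction)
                ):
                    members.add(r.gene)
            lists.append(
                DegList(a=a, b=b, up_in=up_in, genes=frozenset(members),
                        effect_threshold=effect_threshold,
                        fdr_threshold=fdr_threshold, effect_scale=effect_scale)
            )
    return lists


def vs_control_lists(
    results: list[NetworkResult],
    effect_threshold: float = VS_CONTROL_EFFECT_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    effect_scale: str = "linear",
    fdr_direction: str = "corrected",
) -> list[DegList]:
    """Per treatment, genes upregulated vs control above the stricter cutoff.

    Only upregulation counts (signed effect, not |effect|).
    """
    lists = []
    for treatment in TREATMENTS:
        members = set()
        for r in results:
            eff = r.effect.loc[treatment, CONTROL]
            q = r.fdr.loc[treatment, CONTROL]
            if (
                np.isfinite(eff)
                and _passes_effect(eff, effect_threshold, effect_scale)
                and _passes_fdr(q, fdr_threshold, fdr_direction)
            ):
                members.add(r.gene)
        lists.append(
            DegList(a=treatment, b=CONTROL, up_in=treatment,
                    genes=frozenset(members),
                    effect_threshold=effect_threshold,
                    fdr_threshold=fdr_threshold, effect_scale=effect_scale)
        )
    return lists


def derive_signatures(
    pairwise: list[DegList], vs_control: list[DegList]
) -> dict[str, GeneSignature]:
    """Union/intersect/subtract set logic producing the three signatures.

    Returns {"IFN_I": S_IFNa, "IFNb": S_IFNb \\ S_IFNa, "IFN_II": S_IFNg};
    empty signatures are returned with a warning.
    """
    up_vs_control = {lst.up_in: set(lst.genes) for lst in vs_control}
    raw: dict[str, set[str]] = {}
    for treatment in TREATMENTS:
        union = set()
        for lst in pairwise:
            if lst.up_in == treatment:
                union |= lst.genes
        raw[treatment] = union & up_vs_control.get(treatment, set())
    raw["IFNb"] = raw["IFNb"] - raw["IFNa"]

    names = {"IFNa": "IFN_I", "IFNb": "IFNb", "IFNg": "IFN_II"}
    signatures = {}
    for treatment, name in names.items():
        genes = tuple(sorted(raw[treatment]))
        if not genes:
            logger.warning("signature %s is empty", name)
        signatures[name] = GeneSignature(name=name, genes=genes, provenance="derived")
    return signatures


def load_fixture_signatures() -> dict[str, GeneSignature]:
    """The published IFN Aybey signatures bundled with the package.

    IFN_I_Aybey (20 genes), IFNb_Aybey (40 genes) and IFN_II_Aybey (6 genes),
    shipped as a GMT file whose sha256 is verified on load.
    """
    ref = resources.files("ifnsig.data").joinpath(_FIXTURE_FILE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"bundled signature file checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from .io import parse_gmt

    parsed = parse_gmt(raw.decode().splitlines())
    return {
        name: GeneSignature(name=name, genes=sig.genes, provenance="fixture")
        for name, sig in parsed.items()
    }
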