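"""Per-gene network meta-analysis over the treatment graph.

Treatments (control, IFNa, IFNb, IFNg) are nodes; each study's moderated
logFC estimates are weighted edges.  Direct and indirect evidence is combined
by weighted least squares on the node-difference design, solved through the
Moore-Penrose pseudoinverse of the weighted graph Laplacian, which yields a
mutually consistent effect matrix (theta(i,k) = theta(i,j) + theta(j,k)
exactly).  Between-study heterogeneity is estimated by a generalized
DerSimonian-Laird moment estimator on the fixed-effect residual Q statistic,
and the random-effects model refits with edge variances inflated by tau^2.
p-values are Wald/normal; Benjamini-Hochberg correction is applied across
genes separately for each of the six treatment comparisons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dge import CONTROL, TREATMENTS, ContrastEstimate, contrasts_to_table

logger = logging.getLogger(__name__)

#: node order of the 4x4 result matrices
NODES = (CONTROL,) + TREATMENTS

#: the six unordered treatment comparisons of the result matrix
COMPARISONS = tuple(itertools.combinations(NODES, 2))


@dataclass
class TreatmentNetwork:
    """Edge list of one gene's evidence network.

    ``edges`` columns: study, a, b, effect (log2, a minus b), se.
    ``covariance`` is the (edges x edges) covariance of the edge estimates:
    block-diagonal by study, with off-diagonal entries for the correlated
    vs-control contrasts of multi-arm studies (they share the control arm).
    """

    gene: str
    nodes: tuple[str, ...]
    edges: pd.DataFrame
    covariance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not (self.edges["se"] > 0).all():
            raise ValueError(f"{self.gene}: non-positive edge SE")
        if self.covariance is None:
            self.covariance = np.diag(self.edges["se"].to_numpy(float) ** 2)


@dataclass
class NetworkResult:
    """Consistent 4x4 effect/SE/p matrices for one gene.

    Matrices are indexed by :data:`NODES`; entries for conditions absent from
    the gene's network are NaN.  ``fdr`` stays NaN until :func:`adjust_fdr`
    fills it across genes.
    """

    gene: str
    effect: pd.DataFrame
    se: pd.DataFrame
    p: pd.DataFrame
    tau2: float
    model: str
    fdr: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.fdr is None:
            self.fdr = pd.DataFrame(np.nan, index=list(NODES), columns=list(NODES))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(contrasts: list[ContrastEstimate] | pd.DataFrame) -> TreatmentNetwork:
    """Assemble one gene's treatment network from its contrast estimates.

    Contrasts from a multi-arm (>= 3 conditions) study are reduced to the
    (treatment vs control) basis so the shared arm is not double-counted;
    the dropped treatment-treatment contrasts are linear combinations of the
    retained ones by construction.  The covariance between two vs-control
    edges of the same study (they share the control arm) is recovered from
    the pairwise SE by variance triangulation,
    cov(a, b) = (var(a-ctrl) + var(b-ctrl) - var(a-b)) / 2,
    when the study's treatment-treatment contrasts are present; otherwise
    the edges are taken as independent.  Raises if the resulting graph is
    disconnected, listing the components.
    """
    table = contrasts if isinstance(contrasts, pd.DataFrame) else contrasts_to_table(contrasts)
    if len(table) == 0:
        raise ValueError("no contrasts given")
    genes = table["gene"].unique()
    if len(genes) != 1:
        raise ValueError(f"expected contrasts for one gene, got {len(genes)}")
    gene = genes[0]

    kept: list[pd.DataFrame] = []
    blocks: list[np.ndarray] = []
    for study, group in table.groupby("study", sort=False):
        n_conditions = len(set(group["a"]) | set(group["b"]))
        if n_conditions > 2 and (group["b"] == CONTROL).any():
            pair_se = {
                frozenset((a, b)): se
                for a, b, se in zip(group["a"], group["b"], group["se"])
            }
            group = group[group["b"] == CONTROL].reset_index(drop=True)
            arms = list(group["a"])
            block = np.diag(group["se"].to_numpy(float) ** 2)
            for i in range(len(arms)):
                for j in range(i + 1, len(arms)):
                    se_ij = pair_se.get(frozenset((arms[i], arms[j])))
                    if se_ij is None:
                        continue
                    cov = 0.5 * (block[i, i] + block[j, j] - se_ij**2)
                    block[i, j] = block[j, i] = cov
            # guard: a reconstructed block must stay positive definite
            if np.linalg.eigvalsh(block).min() <= 0:
                block = np.diag(np.diag(block))
        else:
            block = np.diag(group["se"].to_numpy(float) ** 2)
        kept.append(group)
        blocks.append(block)
    edges = pd.concat(kept, ignore_index=True)[["study", "a", "b", "effect", "se"]]
    m = len(edges)
    covariance = np.zeros((m, m))
    start = 0
    for block in blocks:
        k = block.shape[0]
        covariance[start:start + k, start:start + k] = block
        start += k

    graph = nx.Graph()
    graph.add_edges_from(zip(edges["a"], edges["b"]))
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        raise ValueError(
            f"{gene}: disconnected treatment network: "
            f"{[sorted(c) for c in components]}"
        )
    nodes = tuple(c for c in NODES if c in graph) + tuple(
        sorted(set(graph) - set(NODES))
    )
    return TreatmentNetwork(gene=gene, nodes=nodes, edges=edges,
                            covariance=covariance)


def _incidence(network: TreatmentNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Edge incidence matrix (edges x nodes) and effect vector."""
    index = {node: i for i, node in enumerate(network.nodes)}
    m = len(network.edges)
    x = np.zeros((m, len(network.nodes)))
    for row, (a, b) in enumerate(zip(network.edges["a"], network.edges["b"])):
        x[row, index[a]] = 1.0
        x[row, index[b]] = -1.0
    return x, network.edges["effect"].to_numpy(float)


def _solve_wls(
    network: TreatmentNetwork, covariance: np.ndarray, model: str, tau2: float
) -> NetworkResult:
    """Generalized least squares on the node-difference design.

    With diagonal edge covariance the normal-equations matrix X'WX is the
    weighted graph Laplacian; block covariances (multi-arm studies) simply
    generalize the weights.  Its pseudoinverse provides node potentials and
    the covariance of all node differences.
    """
    x, y = _incidence(network)
    w = np.linalg.inv(covariance)
    laplacian = x.T @ w @ x
    # the Laplacian of a connected graph has exactly one zero eigenvalue
    lap_pinv = np.linalg.pinv(laplacian, rcond=1e-12, hermitian=True)
    theta = lap_pinv @ (x.T @ (w @ y))

    nodes = list(network.nodes)
    k = len(nodes)
    effect = pd.DataFrame(np.nan, index=list(NODES), columns=list(NODES))
    se = pd.DataFrame(np.nan, index=list(NODES), columns=list(NODES))
    pmat = pd.DataFrame(np.nan, index=list(NODES), columns=list(NODES))
    for i in range(k):
        for j in range(k):
            ni, nj = nodes[i], nodes[j]
            if ni not in NODES or nj not in NODES:
                continue
            eff = theta[i] - theta[j]
            var = lap_pinv[i, i] + lap_pinv[j, j] - 2.0 * lap_pinv[i, j]
            effect.loc[ni, nj] = eff
            if i == j:
                se.loc[ni, nj] = 0.0
                pmat.loc[ni, nj] = 1.0
            else:
                sij = np.sqrt(max(var, 0.0))
                se.loc[ni, nj] = sij
                if sij > 0:
                    pmat.loc[ni, nj] = 2.0 * stats.norm.sf(abs(eff) / sij)
    return NetworkResult(
        gene=network.gene, effect=effect, se=se, p=pmat, tau2=tau2, model=model
    )


def nma_fixed(network: TreatmentNetwork) -> NetworkResult:
    """Fixed-effect (common-effect) network estimates, weights 1/se^2
    (block-generalized for multi-arm studies)."""
    return _solve_wls(network, network.covariance, model="fixed", tau2=0.0)


def estimate_tau2(network: TreatmentNetwork, fixed: NetworkResult) -> float:
    """Generalized DerSimonian-Laird between-study variance.

    tau^2 = max(0, (Q - df) / C) with Q the fixed-effect weighted residual
    sum of squares, df = edges - (nodes - 1) and C = tr(W) - tr(W H), the
    trace correction for the hat matrix H of the weighted solve; tau^2 = 0
    when the network has no replication (df <= 0).  For the scalar
    (single-comparison) network this reduces to the classical
    DerSimonian-Laird C = sum(w) - sum(w^2)/sum(w).
    """
    x, y = _incidence(network)
    w = np.linalg.inv(network.covariance)
    m, k = x.shape
    df = m - (k - 1)
    if df <= 0:
        return 0.0
    laplacian = x.T @ w @ x
    lap_pinv = np.linalg.pinv(laplacian, rcond=1e-12, hermitian=True)
    resid = y - x @ (lap_pinv @ (x.T @ (w @ y)))
    q = float(resid @ w @ resid)
    wx = w @ x
    trace_wh = float(np.trace(wx @ lap_pinv @ wx.T))
    c = float(np.trace(w)) - trace_wh
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def nma_random(network: TreatmentNetwork) -> NetworkResult:
    """Random-effects network estimates: edge variances inflated by tau^2.

    The heterogeneity deviations of different edges are taken as
    independent, so tau^2 enters on the diagonal of the edge covariance.
    Reduces to the fixed-effect fit when tau^2 = 0.
    """
    fixed = nma_fixed(network)
    tau2 = estimate_tau2(network, fixed)
    covariance = network.covariance + tau2 * np.eye(len(network.edges))
    return _solve_wls(network, covariance, model="random", tau2=tau2)


# ---------------------------------------------------------------------------
# across genes
# ---------------------------------------------------------------------------

def run_network_meta(
    contrast_table: pd.DataFrame | list[ContrastEstimate],
    model: str = "random",
) -> list[NetworkResult]:
    """One network meta-analysis per gene, with cross-gene BH correction.

    Genes whose evidence network is disconnected are skipped with a warning.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    table = (
        contrast_table
        if isinstance(contrast_table, pd.DataFrame)
        else contrasts_to_table(contrast_table)
    )
    if len(table) == 0:
        raise ValueError("empty contrast table")
    solver = nma_fixed if model == "fixed" else nma_random
    results: list[NetworkResult] = []
    skipped: list[str] = []
    for gene, group in table.groupby("gene", sort=False):
        try:
            network = build_network(group)
        except ValueError as err:
            skipped.append(gene)
            logger.warning("skipping %s: %s", gene, err)
            continue
        results.append(solver(network))
    if skipped:
        logger.warning("%d genes skipped (disconnected networks)", len(skipped))
    if not results:
        raise ValueError("no gene yielded a connected network")
    return adjust_fdr(results)


def adjust_fdr(results: list[NetworkResult]) -> list[NetworkResult]:
    """Benjamini-Hochberg step-up across genes, per comparison separately.

    Each of the six unordered treatment comparisons is corrected
    independently; q-values are written symmetrically into ``fdr``.
    """
    for a, b in COMPARISONS:
        pvals = np.array([r.p.loc[a, b] for r in results], dtype=float)
        mask = np.isfinite(pvals)
        if not mask.any():
            continue
        qvals = np.full(len(results), np.nan)
        qvals[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.fdr.loc[a, b] = q
            r.fdr.loc[b, a] = q
    return results


def results_to_table(results: list[NetworkResult]) -> pd.DataFrame:
    """Long-format table (gene, a, b, effect, se, p, q, tau2) over the six
    unordered comparisons."""
    rows = []
    for r in results:
        for a, b in COMPARISONS:
            rows.append(
                (r.gene, a, b, r.effect.loc[a, b], r.se.loc[a, b],
                 r.p.loc[a, b], r.fdr.loc[a, b], r.tau2)
            )
    return pd.DataFrame(
        rows, columns=["gene", "a", "b", "effect", "se", "p", "q", "tau2"]
    )
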