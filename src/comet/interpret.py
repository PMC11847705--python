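"""Post-hoc model interpretation and representation analyses.

Covers the discovery side of the framework: integrated-gradients analyte
attributions (path integral from a baseline omics vector with the patient's
own EHR sequence held fixed), counts of Bonferroni-significant correlations
between EHR latent dimensions and analytes (the alignment analysis),
feature-correlation maps embedded in 2-D, per-branch intermediate-node
performance, and function-space training trajectories (models compared by
their concatenated outputs on a fixed record set, not by raw parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score

from .comet_net import ModelData, MultimodalNet
from .nn import Tensor, concat

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionMatrix", "AlignmentResult", "CorrelationMap",
    "FunctionSpaceTrace", "integrated_gradients", "omics_attributions",
    "latent_alignment", "correlation_map", "intermediate_node_performance",
    "function_space_trace",
]


# ---------------------------------------------------------------------------
# integrated gradients

def integrated_gradients(fn, x: np.ndarray, baseline: np.ndarray | None = None,
                         m: int = 128) -> np.ndarray:
    """Path-integral attributions for a differentiable ``fn``.

    ``fn`` maps a ``Tensor`` of shape (m, P) to a ``Tensor`` of shape (m,);
    the path gradient is averaged at the m midpoints (s - 1/2)/m of the
    straight line from ``baseline`` (default zero vector) to ``x``, making
    the completeness identity sum(attr) = f(x) - f(baseline) hold to
    O(1/m^2).
    """
    x = np.asarray(x, float)
    if baseline is None:
        baseline = np.zeros_like(x)
    alphas = (np.arange(1, m + 1) - 0.5) / m
    points = baseline[None, :] + alphas[:, None] * (x - baseline)[None, :]
    pts = Tensor(points, requires_grad=True)
    out = fn(pts)
    out.sum().backward()
    avg_grad = pts.grad.mean(axis=0)
    return (x - baseline) * avg_grad


def _omics_fn(net: MultimodalNet, h_row: np.ndarray):
    """f(omics) for one sample with the EHR latent state held fixed."""
    def fn(xs: Tensor) -> Tensor:
        m = xs.shape[0]
        h = Tensor(np.repeat(h_row[None, :], m, axis=0))
        p_ehr = net.ehr_head(h)
        p_om = net.omics_head(xs)
        p_joint = net.joint_head(concat([h, xs], axis=1))
        raw = net.combiner(concat([p_ehr, p_om, p_joint], axis=1)).reshape(m)
        return raw.sigmoid() if net.task == "classification" else raw
    return fn


@dataclass
class AttributionMatrix:
    attributions: np.ndarray        # (n_samples, P)
    importance: np.ndarray          # per-analyte mean absolute attribution
    completeness_residual: np.ndarray  # |sum(attr) - (f(x) - f(baseline))|


def omics_attributions(net: MultimodalNet, data: ModelData,
                       baseline: np.ndarray | None = None,
                       m: int = 128) -> AttributionMatrix:
    """Integrated-gradients attributions for every record's omics vector.

    The default baseline is the zero vector, i.e. the cohort mean on
    standardized analytes. EHR inputs stay fixed at each record's own
    sequence.
    """
    h_all = net.forward(data)[2].data
    P = data.omics.shape[1]
    if baseline is None:
        baseline = np.zeros(P)
    attrs = np.zeros((len(data), P))
    resid = np.zeros(len(data))
    for i in range(len(data)):
        fn = _omics_fn(net, h_all[i])
        attrs[i] = integrated_gradients(fn, data.omics[i], baseline, m)
        fx = float(fn(Tensor(data.omics[i][None, :])).data[0])
        fb = float(fn(Tensor(baseline[None, :])).data[0])
        resid[i] = abs(attrs[i].sum() - (fx - fb))
    return AttributionMatrix(attributions=attrs,
                             importance=np.abs(attrs).mean(axis=0),
                             completeness_residual=resid)


# ---------------------------------------------------------------------------
# correlation analyses

def _corr_with_p(Xa: np.ndarray, Xb: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlations and two-sided t p-values; constant
    columns give r = 0, p = 1."""
    n = Xa.shape[0]
    sa = Xa.std(axis=0)
    sb = Xb.std(axis=0)
    Za = (Xa - Xa.mean(axis=0)) / np.where(sa == 0, 1.0, sa)
    Zb = (Xb - Xb.mean(axis=0)) / np.where(sb == 0, 1.0, sb)
    r = Za.T @ Zb / n
    r[sa == 0, :] = 0.0
    r[:, sb == 0] = 0.0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[sa == 0, :] = 1.0
    p[:, sb == 0] = 1.0
    return r, p


@dataclass
class AlignmentResult:
    corr: np.ndarray             # (d, P)
    pvals: np.ndarray
    threshold: float             # Bonferroni-adjusted per-test level
    n_significant: int
    per_analyte_fraction: np.ndarray  # fraction of latent dims significant


def latent_alignment(latents: np.ndarray, omics: np.ndarray,
                     alpha: float = 0.05) -> AlignmentResult:
    """Count Bonferroni-significant latent-dimension x analyte correlations.

    The correction family is the full d x P grid of tests.
    """
    if latents.shape[0] != omics.shape[0]:
        raise ValueError("latents and omics need matched rows")
    d, P = latents.shape[1], omics.shape[1]
    r, p = _corr_with_p(latents, omics)
    thr = alpha / (d * P)
    sig = p < thr
    return AlignmentResult(corr=r, pvals=p, threshold=thr,
                           n_significant=int(sig.sum()),
                           per_analyte_fraction=sig.mean(axis=0))


@dataclass
class CorrelationMap:
    coords: np.ndarray              # (q, 2) embedding of correlation profiles
    outcome_corr: np.ndarray        # per-feature correlation with outcome
    sig_pairs_per_analyte: np.ndarray
    max_abs_corr_per_ehr: np.ndarray
    feature_names: list[str]
    is_ehr: np.ndarray


def _tsne(X: np.ndarray, seed: int, perplexity: float = 30.0) -> np.ndarray:
    perplexity = min(perplexity, max(1.0, (X.shape[0] - 1) / 3))
    return TSNE(n_components=2, random_state=seed, init="random",
                perplexity=perplexity).fit_transform(X)


def correlation_map(features: np.ndarray, feature_names: list[str],
                    is_ehr: np.ndarray, outcome: np.ndarray,
                    alpha: float = 0.05, seed: int = 0,
                    embed: bool = True) -> CorrelationMap:
    """Feature-correlation structure across modalities.

    Embeds each feature's row of the full correlation matrix in 2-D (so
    features with similar correlation profiles sit together), computes each
    feature's univariate outcome correlation, and counts
    Bonferroni-significant EHR x analyte pairs (family = all cross-modality
    pairs), plus each EHR feature's maximum absolute correlation over
    analytes.
    """
    q = features.shape[1]
    if q < 3:
        raise ValueError("need at least 3 features")
    is_ehr = np.asarray(is_ehr, bool)
    R, _ = _corr_with_p(features, features)
    coords = _tsne(R, seed) if embed else np.zeros((q, 2))
    oc, _ = _corr_with_p(features, outcome[:, None])
    ehr_cols = features[:, is_ehr]
    om_cols = features[:, ~is_ehr]
    r_x, p_x = _corr_with_p(ehr_cols, om_cols)
    thr = alpha / max(1, r_x.size)
    sig = p_x < thr
    return CorrelationMap(coords=coords, outcome_corr=oc[:, 0],
                          sig_pairs_per_analyte=sig.sum(axis=0),
                          max_abs_corr_per_ehr=(np.abs(r_x).max(axis=1)
                                                if r_x.size else np.zeros(0)),
                          feature_names=list(feature_names), is_ehr=is_ehr)


# ---------------------------------------------------------------------------
# intermediate nodes and function space

def intermediate_node_performance(net: MultimodalNet, data: ModelData,
                                  task: str) -> dict[str, float]:
    """Evaluate each branch score (ehr / omics / joint) against the outcome:
    Pearson r for regression, AUROC for classification."""
    branch = net.branch_values(data)
    out = {}
    for j, name in enumerate(("ehr", "omics", "joint")):
        v = branch[:, j]
        if task == "regression":
            out[name] = (float(stats.pearsonr(data.y, v)[0])
                         if np.std(v) > 0 else float("nan"))
        else:
            out[name] = float(roc_auc_score(data.y, v))
    return out


@dataclass
class FunctionSpaceTrace:
    views: dict[str, np.ndarray]     # view -> (n_snapshots_total, n_records)
    coords: dict[str, np.ndarray]    # view -> (n_snapshots_total, 2)
    labels: list[tuple[str, int]]    # (model label, epoch) per row


def function_space_trace(groups: list[tuple[str, MultimodalNet, list[dict]]],
                         data: ModelData, seed: int = 0,
                         embed: bool = True) -> FunctionSpaceTrace:
    """Compare training trajectories in function space.

    ``groups`` holds (label, network, per-epoch state snapshots); every
    snapshot is loaded into the network, run over all records, and its
    concatenated outputs become one row per view (overall prediction plus
    the three branch scores). Rows are embedded in 2-D with a fixed seed.
    """
    total = sum(len(snaps) for _, _, snaps in groups)
    if total < 2:
        raise ValueError("need at least 2 snapshots")
    views: dict[str, list[np.ndarray]] = {v: [] for v in
                                          ("overall", "ehr", "omics", "joint")}
    labels: list[tuple[str, int]] = []
    for label, net, snaps in groups:
        saved = net.state_dict()
        for epoch, state in enumerate(snaps):
            net.load_state_dict(state)
            yhat, branch, _ = net.forward(data)
            views["overall"].append(yhat.data.copy())
            for j, name in enumerate(("ehr", "omics", "joint")):
                views[name].append(branch.data[:, j].copy())
            labels.append((label, epoch))
        net.load_state_dict(saved)
    mats = {v: np.stack(rows) for v, rows in views.items()}
    coords = {v: (_tsne(m, seed) if embed else np.zeros((m.shape[0], 2)))
              for v, m in mats.items()}
    return FunctionSpaceTrace(views=mats, coords=coords, labels=labels)
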