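"""Independent brute-force reference implementations used only by tests.

Each function recomputes a statistic from first principles (exhaustive
pair counting, explicit surface-distance search, permutation resampling)
so the package implementations are checked against a second, slower
route.
"""

from __future__ import annotations

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """ROC AUC by exhaustive positive/negative pair comparison."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def average_precision_hand(scores, labels) -> float:
    """AP as the step-wise sum of precision at each recall increment."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tp = 0
    ap = 0.0
    n_pos = labels.sum()
    for k, lab in enumerate(labels, start=1):
        if lab == 1:
            tp += 1
            ap += tp / k
    return ap / n_pos


def kappa_closed_form(a, b) -> float:
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    p_o = (a == b).mean()
    p_e = a.mean() * b.mean() + (1 - a.mean()) * (1 - b.mean())
    return (p_o - p_e) / (1 - p_e)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: in the mask with any face-neighbour outside it
    (voxels on the array border count as boundary)."""
    out = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        x, y, z = idx
        boundary = False
        for dx, dy, dz in (
            (1, 0, 0),
            (-1, 0, 0),
            (0, 1, 0),
            (0, -1, 0),
            (0, 0, 1),
            (0, 0, -1),
        ):
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (
                0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]
            ):
                boundary = True
                break
            if not mask[nx, ny, nz]:
                boundary = True
                break
        if boundary:
            out.append(idx)
    return np.array(out).reshape(-1, 3)


def nsd_brute_force(mask_a, mask_b, tol, spacing) -> float:
    """NSD via explicit pairwise surface distances."""
    sa = surface_voxels(np.asarray(mask_a, bool))
    sb = surface_voxels(np.asarray(mask_b, bool))
    if len(sa) == 0 and len(sb) == 0:
        return 1.0
    if len(sa) == 0 or len(sb) == 0:
        return 0.0
    sp = np.asarray(spacing, float)
    a_mm = sa * sp
    b_mm = sb * sp
    d_ab = np.sqrt(((a_mm[:, None, :] - b_mm[None, :, :]) ** 2).sum(-1))
    close_a = (d_ab.min(axis=1) <= tol).sum()
    close_b = (d_ab.min(axis=0) <= tol).sum()
    return (close_a + close_b) / (len(sa) + len(sb))


def delong_p_permutation(s1, s2, labels, n_rep=10_000, seed=0) -> float:
    """Two-sided p for the paired AUC difference by label-preserving
    score-swap permutation: each case's two scores are exchanged with
    probability 1/2."""
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)

    def auc(s):
        return auc_pair_counting(s, labels)

    observed = abs(auc(s1) - auc(s2))
    n = len(labels)
    count = 0
    for _ in range(n_rep):
        swap = rng.random(n) < 0.5
        a = np.where(swap, s2, s1)
        b = np.where(swap, s1, s2)
        if abs(auc(a) - auc(b)) >= observed - 1e-12:
            count += 1
    return count / n_rep


def best_f1_exhaustive(scores, labels):
    """Max achievable F1 over all decision rules of the form score >= t."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    candidates = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    best = -1.0
    for t in candidates:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        best = max(best, f1)
    return best


def _delong_z_rows(a: np.ndarray, b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised DeLong z statistic for B paired (a_row, b_row) score sets."""
    from scipy.stats import rankdata

    labels = np.asarray(labels, int)
    m = int(labels.sum())
    n_neg = len(labels) - m

    def components(s):
        all_ranks = rankdata(s, axis=1)
        pos_ranks = rankdata(s[:, labels == 1], axis=1)
        neg_ranks = rankdata(s[:, labels == 0], axis=1)
        v_pos = (all_ranks[:, labels == 1] - pos_ranks) / n_neg
        v_neg = 1.0 - (all_ranks[:, labels == 0] - neg_ranks) / m
        return v_pos, v_neg

    vpa, vna = components(a)
    vpb, vnb = components(b)
    auc_a, auc_b = vpa.mean(axis=1), vpb.mean(axis=1)

    def cov_terms(x, y):
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        return (xc * yc).sum(axis=1) / (x.shape[1] - 1)

    var = (
        cov_terms(vpa, vpa) + cov_terms(vpb, vpb) - 2 * cov_terms(vpa, vpb)
    ) / m + (cov_terms(vna, vna) + cov_terms(vnb, vnb) - 2 * cov_terms(vna, vnb)) / n_neg
    diff = auc_a - auc_b
    z = np.zeros_like(diff)
    ok = var > 0
    z[ok] = diff[ok] / np.sqrt(var[ok])
    z[~ok] = np.where(diff[~ok] == 0, 0.0, np.inf * np.sign(diff[~ok]))
    return z


def delong_p_studentized_swap(s1, s2, labels, n_rep=10_000, seed=0) -> float:
    """Permutation analogue of the asymptotic paired-AUC test: each case's
    two scores are swapped with probability 1/2 and the studentized statistic
    is recomputed; mid-p tie handling makes the discrete permutation null
    comparable to a continuous approximation."""
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    n = len(labels)
    z_obs = abs(_delong_z_rows(s1[None, :], s2[None, :], labels)[0])
    swap = rng.random((n_rep, n)) < 0.5
    a = np.where(swap, s2[None, :], s1[None, :])
    b = np.where(swap, s1[None, :], s2[None, :])
    z = np.abs(_delong_z_rows(a, b, labels))
    strict = float((z > z_obs + 1e-12).mean())
    ties = float((np.abs(z - z_obs) <= 1e-12).mean())
    return strict + 0.5 * ties
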