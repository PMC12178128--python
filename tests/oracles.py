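"""Independent oracles used only by the test suite.

Each oracle reaches the quantity under test by a different route than the
implementation: closed-form quaternion superposition instead of SVD Kabsch, a
dense rotation-grid search instead of fragment-seeded refinement for
TM-score, and exhaustive pair enumeration for lDDT.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_rmsd(mobile: np.ndarray, ref: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's closed-form quaternion method."""
    xm = mobile - mobile.mean(axis=0)
    xr = ref - ref.mean(axis=0)
    sxx = xm.T @ xr
    sxx_t = sxx.T
    a = np.empty((4, 4))
    a[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    a[0, 1] = a[1, 0] = sxx_t[1, 2] - sxx_t[2, 1]
    a[0, 2] = a[2, 0] = sxx_t[2, 0] - sxx_t[0, 2]
    a[0, 3] = a[3, 0] = sxx_t[0, 1] - sxx_t[1, 0]
    a[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    a[1, 2] = a[2, 1] = sxx[0, 1] + sxx[1, 0]
    a[1, 3] = a[3, 1] = sxx[0, 2] + sxx[2, 0]
    a[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    a[2, 3] = a[3, 2] = sxx[1, 2] + sxx[2, 1]
    a[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam_max = np.linalg.eigvalsh(a)[-1]
    e0 = float(np.sum(xm ** 2) + np.sum(xr ** 2))
    msd = max(0.0, (e0 - 2.0 * lam_max) / len(xm))
    return float(np.sqrt(msd))


def _tm_sum(xm: np.ndarray, xr: np.ndarray, d0: float) -> float:
    d2 = np.sum((xm - xr) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))))


def tm_score_grid_oracle(xm: np.ndarray, xr: np.ndarray, l_norm: int,
                         d0: float, n_grid: int = 40,
                         n_polish: int = 150) -> float:
    """Brute-force TM-score: dense Euler-angle rotation grid crossed with a
    translation brute force (centroid match plus every translation that lays
    one residue exactly on its partner), then derivative-free polish of the
    best candidates over all six rigid degrees of freedom.

    The default 9-degree rotation step is finer than the basin width of the
    d0-floored objective on short chains (roughly d0 / max radius), so every
    basin receives at least one grid candidate.
    """
    angles = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    betas = np.linspace(0.0, np.pi, n_grid // 2 + 1)
    eulers = np.array(list(itertools.product(angles, betas, angles)))
    rots = Rotation.from_euler("zyz", eulers).as_matrix()
    n = len(xm)

    rotated = np.einsum("sij,nj->sni", rots, xm)        # (S, n, 3)
    cr = xr.mean(axis=0)
    # translation seeds per rotation: centroid match + per-residue alignment
    cand_trans = np.concatenate([
        (cr - rotated.mean(axis=1))[:, None, :],        # (S, 1, 3)
        xr[None, :, :] - rotated,                       # (S, n, 3)
    ], axis=1)                                          # (S, n+1, 3)
    # score all (rotation, translation) pairs vectorized
    moved = rotated[:, None, :, :] + cand_trans[:, :, None, :]   # (S, T, n, 3)
    d2 = np.sum((moved - xr[None, None]) ** 2, axis=-1)
    scores = np.sum(1.0 / (1.0 + d2 / (d0 * d0)), axis=-1)       # (S, T)

    def neg(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        pts = xm @ rot.T + params[3:]
        return -_tm_sum(pts, xr, d0)

    flat = np.argsort(scores, axis=None)[::-1][:n_polish]
    best = float(scores.max())
    polished: list[tuple[float, np.ndarray]] = []
    for idx in flat:
        k, t = np.unravel_index(idx, scores.shape)
        rotvec = Rotation.from_matrix(rots[k]).as_rotvec()
        x0 = np.concatenate([rotvec, cand_trans[k, t]])
        # cheap smooth descent into each candidate's basin ...
        res = minimize(neg, x0, method="L-BFGS-B")
        polished.append((-float(res.fun), np.asarray(res.x)))
        best = max(best, -float(res.fun))
    # ... then a tight derivative-free finish on the best few basins
    polished.sort(key=lambda c: -c[0])
    for _, x0 in polished[:8]:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000})
        best = max(best, -float(res.fun))
    return min(1.0, best / l_norm)


def lddt_bruteforce(model_ca: np.ndarray, ref_ca: np.ndarray,
                    residue_idx: np.ndarray, inclusion_radius: float = 15.0,
                    thresholds=(0.5, 1.0, 2.0, 4.0)) -> tuple[float, np.ndarray]:
    """Exhaustive pair-enumeration lDDT on CA coordinates."""
    n = len(ref_ca)
    per_pairs: list[list[float]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j or abs(int(residue_idx[i]) - int(residue_idx[j])) < 2:
                continue
            dr = float(np.linalg.norm(ref_ca[i] - ref_ca[j]))
            if dr > inclusion_radius:
                continue
            dm = float(np.linalg.norm(model_ca[i] - model_ca[j]))
            diff = abs(dm - dr)
            frac = sum(diff <= t for t in thresholds) / len(thresholds)
            per_pairs[i].append(frac)
    per_res = np.array([np.mean(p) if p else np.nan for p in per_pairs])
    valid = ~np.isnan(per_res)
    return float(per_res[valid].mean()), per_res


def spearman_bruteforce(x, y) -> float:
    """Mid-rank assignment by direct enumeration, then textbook Pearson."""
    def midranks(v):
        v = list(map(float, v))
        out = []
        for a in v:
            less = sum(b < a for b in v)
            equal = sum(b == a for b in v)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx = midranks(x)
    ry = midranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den
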