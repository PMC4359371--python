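"""Independent oracles used by the test suite.

These deliberately avoid the closed-form Kabsch path used by the package:
rotations are found by coarse sampling of rotation space followed by local
refinement, axes by a grid over the unit sphere, and distances by the
textbook point-to-line formula.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def point_line_distance(p: np.ndarray, point: np.ndarray, direction: np.ndarray) -> float:
    """Distance from p to the line through `point` along `direction`."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    v = np.asarray(p, dtype=float) - np.asarray(point, dtype=float)
    return float(np.linalg.norm(v - np.dot(v, d) * d))


def brute_force_rotation(P: np.ndarray, Q: np.ndarray, seed: int = 0, n_samples: int = 600) -> np.ndarray:
    """Best proper rotation P -> Q by sampled search + local refinement."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)

    def cost_rotvec(rv: np.ndarray) -> float:
        R = Rotation.from_rotvec(rv).as_matrix()
        return float(((P @ R.T - Q) ** 2).sum())

    rng = np.random.default_rng(seed)
    candidates = [np.zeros(3)] + list(Rotation.random(n_samples, rng=rng).as_rotvec())
    best = min(candidates, key=cost_rotvec)
    res = minimize(cost_rotvec, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000})
    return Rotation.from_rotvec(res.x).as_matrix()


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def brute_force_ring_axis(pairs_moving: np.ndarray, pairs_target: np.ndarray,
                          center: np.ndarray, chi_deg: float,
                          n_grid: int = 400) -> np.ndarray:
    """Axis direction of the subunit permutation by exhaustive search.

    Minimizes the RMSD between target atoms and moving atoms rotated by
    chi_deg about the candidate axis through `center`; grid over the unit
    sphere, then Nelder-Mead refinement in spherical coordinates.
    """
    P = np.asarray(pairs_moving, dtype=float) - center
    Q = np.asarray(pairs_target, dtype=float) - center
    chi = math.radians(chi_deg)

    def cost_dir(d: np.ndarray) -> float:
        d = d / np.linalg.norm(d)
        R = Rotation.from_rotvec(d * chi).as_matrix()
        return float(((P @ R.T - Q) ** 2).sum())

    grid = fibonacci_sphere(n_grid)
    best = min(grid, key=cost_dir)
    th0 = math.acos(np.clip(best[2], -1, 1))
    ph0 = math.atan2(best[1], best[0])

    def cost_sph(x) -> float:
        th, ph = x
        return cost_dir(np.array([
            math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)
        ]))

    res = minimize(cost_sph, [th0, ph0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 10000})
    th, ph = res.x
    return np.array([
        math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)
    ])


def ring_pairs(model, chains):
    """Consecutive-chain atom pairs by (residue, icode, atom name) key."""
    by_chain = {c: {} for c in chains}
    for a in model.atoms:
        if a.chain_id in by_chain:
            by_chain[a.chain_id][(a.residue_number, a.insertion_code, a.atom_name)] = a.position
    P, Q = [], []
    n = len(chains)
    for k in range(n):
        src, dst = by_chain[chains[k]], by_chain[chains[(k + 1) % n]]
        for key in sorted(src.keys() & dst.keys()):
            P.append(src[key])
            Q.append(dst[key])
    return np.asarray(P), np.asarray(Q)


def axis_angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two axis directions, sign-insensitive."""
    u = np.asarray(u, dtype=float) / np.linalg.norm(u)
    v = np.asarray(v, dtype=float) / np.linalg.norm(v)
    return math.degrees(math.acos(np.clip(abs(float(np.dot(u, v))), 0.0, 1.0)))
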