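"""Independent reference implementations used to check package results.

Everything here is written as plain double loops over atoms, sharing no code
with the package internals, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def rmsd_oracle(names_a, coords_a, names_b, coords_b):
    """Root-mean-square deviation over name-matched atoms, no superposition."""
    index_b = {n: i for i, n in enumerate(names_b)}
    sq = [
        sum((coords_a[i][k] - coords_b[index_b[n]][k]) ** 2 for k in range(3))
        for i, n in enumerate(names_a)
    ]
    return math.sqrt(sum(sq) / len(sq))


def classify_oracle(structure, ligand, waters, cutoff=3.0):
    """Loose/tight water labels by direct distance counting (all atoms)."""
    labels = []
    for w in range(len(waters)):
        o = waters.oxygens[w]
        n_p = sum(
            1
            for i in range(len(structure))
            if np.linalg.norm(structure.coords[i] - o) <= cutoff
        )
        n_l = sum(
            1
            for i in range(len(ligand))
            if np.linalg.norm(ligand.coords[i] - o) <= cutoff
        )
        if n_p >= 2 and n_l >= 2:
            labels.append("tight")
        elif n_p >= 1 and n_l >= 1:
            labels.append("loose")
        else:
            labels.append("none")
    return labels


def _flat_atoms(pose):
    """Flatten a pose into per-atom records mirroring the scorer's typing.

    Returns a list of dicts with partner (0 protein, 1 ligand, 2 water),
    coord, heavy, vdw, role, and donor-hydrogen coordinates.
    """
    atoms = []
    st = pose.structure
    for i in range(len(st)):
        atoms.append(
            {
                "partner": 0,
                "coord": st.coords[i],
                "heavy": not st.is_hydrogen[i],
                "vdw": st.vdw[i],
                "role": st.roles[i],
                "hs": [],
            }
        )
    # protein donor hydrogens: H atoms within 1.25 A, at most two, index order
    h_idx = [i for i in range(len(st)) if st.is_hydrogen[i]]
    for rec, i in zip(atoms, range(len(st))):
        if st.is_hydrogen[i]:
            continue
        close = [
            st.coords[h]
            for h in h_idx
            if np.linalg.norm(st.coords[h] - st.coords[i]) <= 1.25
        ]
        rec["hs"] = close[:2]

    lig = pose.ligand
    adj = lig.neighbors()
    for i in range(len(lig)):
        hs = [lig.coords[n] for n in adj[i] if lig.is_hydrogen[n]][:2]
        atoms.append(
            {
                "partner": 1,
                "coord": lig.coords[i],
                "heavy": not lig.is_hydrogen[i],
                "vdw": lig.vdw[i],
                "role": lig.roles[i],
                "hs": hs,
            }
        )
    for w in range(len(pose.waters)):
        atoms.append(
            {
                "partner": 2,
                "coord": pose.waters.oxygens[w],
                "heavy": True,
                "vdw": 1.52,
                "role": "both",
                "hs": [pose.waters.hydrogens[w, 0], pose.waters.hydrogens[w, 1]],
            }
        )
        for h in range(2):
            atoms.append(
                {
                    "partner": 2,
                    "coord": pose.waters.hydrogens[w, h],
                    "heavy": False,
                    "vdw": 1.20,
                    "role": "none",
                    "hs": [],
                }
            )
    return atoms


def _lj_pair(d, rmin, w):
    """(weighted_attractive_plus_repulsive,) for one heavy pair."""
    if d > w.cutoff:
        return 0.0
    ratio6 = (rmin / d) ** 6 if d > 1e-9 else 0.0
    lj = w.epsilon * (ratio6 * ratio6 - 2.0 * ratio6)
    if d < rmin:
        atr = -w.epsilon
        rep = min(lj + w.epsilon, w.rep_cap)
    else:
        atr = lj
        rep = 0.0
    return w.attractive * atr + w.repulsive * rep


def _hb_pair(donor, acceptor, w):
    """Weighted hydrogen-bond energy for one ordered donor->acceptor pair."""
    d = float(np.linalg.norm(donor["coord"] - acceptor["coord"]))
    f = (w.hb_d_zero - d) / (w.hb_d_zero - w.hb_d_full)
    f = min(1.0, max(0.0, f))
    if f <= 0.0:
        return 0.0
    if not donor["hs"]:
        g = 1.0
    else:
        g = 0.0
        for h in donor["hs"]:
            v1 = donor["coord"] - h
            v2 = acceptor["coord"] - h
            c = float(v1 @ v2) / (
                float(np.linalg.norm(v1)) * float(np.linalg.norm(v2)) + 1e-12
            )
            g = max(g, min(1.0, max(0.0, (-0.5 - c) / 0.5)))
    return w.hbond * (-f * g)


def cross_partner_interface(pose, weights):
    """(interface_ligand, interface_water): brute-force cross-partner sums.

    Cross-partner pairs carry no bonded exclusions, so this is a plain double
    loop over all atom pairs with exactly one member in the partner.
    """
    atoms = _flat_atoms(pose)
    n = len(atoms)
    iface_lig = 0.0
    iface_wat = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = atoms[i], atoms[j]
            cross_lig = (a["partner"] == 1) != (b["partner"] == 1)
            cross_wat = (a["partner"] == 2) != (b["partner"] == 2)
            if not (cross_lig or cross_wat):
                continue
            e = 0.0
            if a["heavy"] and b["heavy"]:
                d = float(np.linalg.norm(a["coord"] - b["coord"]))
                e += _lj_pair(d, a["vdw"] + b["vdw"], weights)
            for donor, acceptor in ((a, b), (b, a)):
                if not (donor["heavy"] and acceptor["heavy"]):
                    continue
                if donor["role"] not in ("donor-heavy", "both"):
                    continue
                if acceptor["role"] not in ("acceptor", "both"):
                    continue
                e += _hb_pair(donor, acceptor, weights)
            if cross_lig:
                iface_lig += e
            if cross_wat:
                iface_wat += e
    return iface_lig, iface_wat


def decoy_oracle(ligand, inner, outer, spacing, margin=4.0):
    """Exhaustive decoy-water placement over the full grid box.

    Mirrors the declared algorithm with naive full enumeration: grid points
    at integer multiples of ``spacing`` over the ligand bounding box plus
    ``margin``, shell membership per polar atom, vdW occupancy removal, and
    a minimum-mean-distance central point with lexicographic tie-break.
    """
    lo = ligand.coords.min(axis=0) - margin
    hi = ligand.coords.max(axis=0) + margin
    shifted = ligand.coords - lo
    bounds = hi - lo
    n_pts = np.floor(bounds / spacing).astype(int) + 1
    axes = [np.arange(n_pts[k]) * spacing for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    # occupancy: inside any ligand atom's vdW sphere
    occupied = np.zeros(len(grid), dtype=bool)
    for i in range(len(ligand)):
        d = np.linalg.norm(grid - shifted[i], axis=1)
        occupied |= d < ligand.vdw[i]

    oxygens = []
    for i in range(len(ligand)):
        if ligand.is_hydrogen[i]:
            continue
        if ligand.roles[i] not in ("donor-heavy", "acceptor", "both"):
            continue
        d = np.linalg.norm(grid - shifted[i], axis=1)
        keep = (d >= inner) & (d <= outer) & ~occupied
        pts = grid[keep]
        if len(pts) == 0:
            continue
        if len(pts) == 1:
            best = pts[0]
        else:
            sums = np.array(
                [np.linalg.norm(pts - p, axis=1).sum() for p in pts]
            )
            m = sums.min()
            cand = pts[sums <= m + 1e-9]
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
            best = cand[order[0]]
        oxygens.append(best + lo)
    return np.array(oxygens).reshape(-1, 3)


def binomial_tail_enum(n, p, k):
    """P(X >= k) by direct summation with math.comb (small n only)."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )
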