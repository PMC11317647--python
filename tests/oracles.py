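"""Independent brute-force oracles the implementation is checked against.

Deliberately written with different algorithms from the package code:
crossing counting scans a per-frame region-label string with a regular
expression instead of running a state machine; periodic distances enumerate
all 27 periodic images instead of using the analytic minimum-image formula.
"""

import re

import numpy as np


def min_image_27(a, b, box):
    """Minimum distance between two points over the 27 periodic images."""
    a, b, box = (np.asarray(x, dtype=float) for x in (a, b, box))
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def brute_force_coordination(frame, ion, partners, cutoff):
    """Count partners strictly within cutoff of the ion, via 27-image scan."""
    n = 0
    for p in partners:
        if p == ion:
            continue
        if min_image_27(frame.positions[ion], frame.positions[p], frame.box) < cutoff:
            n += 1
    return n


def brute_force_crossings(traj, pore, species="cation", margin=2.0):
    """Count directional pore traversals by regex over region labels.

    Per frame each ion is labelled L (luminal bulk), C (cytosolic bulk),
    M (between the planes and inside the cylinder) or X (between the planes
    but radially outside).  A forward event is a maximal run matching
    ``LM+C``; a reverse event matches ``CM+L``.
    """
    ax = np.asarray(pore.axis, dtype=float)
    s = pore.luminal_side
    u_sf, u_gate = s * pore.z_sf, s * pore.z_gate
    ions = np.flatnonzero(traj.topology.species == species)
    n_fwd = n_rev = 0
    for ion in ions:
        labels = []
        for fr in traj.frames:
            center = fr.box / 2.0
            d = fr.positions[ion] - center
            d -= fr.box * np.round(d / fr.box)
            u = s * float(d @ ax)
            radial = float(np.linalg.norm(d - (d @ ax) * ax))
            if u > u_sf + margin:
                labels.append("L")
            elif u < u_gate - margin:
                labels.append("C")
            elif radial <= pore.cylinder_radius:
                labels.append("M")
            else:
                labels.append("X")
        seq = "".join(labels)
        n_fwd += len(re.findall(r"L+M+C", seq))
        n_rev += len(re.findall(r"C+M+L", seq))
    return n_fwd, n_rev
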