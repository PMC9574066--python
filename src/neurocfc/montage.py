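"""10-20 / 10-10 scalp montage geometry on a spherical head model.

Electrode positions are constructed on a unit sphere from the standard 10-20
arc fractions (vertex Cz at the pole, the outer Fpz-T7-Oz-T8 ring at a polar
angle of 72 degrees) with intermediate 10-10 sites placed by spherical
interpolation along the corresponding rows.  Positions are flattened with an
azimuthal-equidistant projection (2-D radius = head radius x polar angle in
radians), which preserves scalp arc distance from the vertex and gives a
faithful small-scale approximation to geodesic inter-electrode distance.

The default head radius (9.2 cm) matches an average adult head; with it,
neighbouring 20%-step electrodes sit 5.5-6.5 cm apart, so the 6-cm spatial
adjacency rule used by the channel-level cluster statistics yields a
connected but non-complete neighbour graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DEFAULT_CHANNELS", "standard_positions", "adjacency_matrix", "HEAD_RADIUS_CM"]

HEAD_RADIUS_CM = 9.2

DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]


def _sph(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector; polar angle from vertex, azimuth from nose toward the right."""
    th, ph = np.deg2rad(polar_deg), np.deg2rad(azim_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between unit vectors."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _build_unit_sphere() -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    p["Cz"] = _sph(0, 0)
    # midline (20% arc steps of the nasion-inion line)
    p["Fpz"], p["Fz"] = _sph(72, 0), _sph(36, 0)
    p["Pz"], p["Oz"] = _sph(36, 180), _sph(72, 180)
    # outer ring at polar 72 deg, 10% circumference steps
    ring = {"Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
            "P7": -126, "P8": 126, "O1": -162, "O2": 162}
    for name, az in ring.items():
        p[name] = _sph(72, az)
    # central coronal line
    p["C3"], p["C4"] = _sph(36, -90), _sph(36, 90)
    # lateral standard sites: midway along the frontal / parietal arcs
    p["F3"] = _slerp(p["Fz"], p["F7"], 0.5)
    p["F4"] = _slerp(p["Fz"], p["F8"], 0.5)
    p["P3"] = _slerp(p["Pz"], p["P7"], 0.5)
    p["P4"] = _slerp(p["Pz"], p["P8"], 0.5)
    # 10-10 intermediate rows via interpolation from midline to the ring
    p["FCz"] = _slerp(p["Fz"], p["Cz"], 0.5)
    p["CPz"] = _slerp(p["Pz"], p["Cz"], 0.5)
    p["FT7"] = _slerp(p["F7"], p["T7"], 0.5)
    p["FT8"] = _slerp(p["F8"], p["T8"], 0.5)
    p["TP7"] = _slerp(p["P7"], p["T7"], 0.5)
    p["TP8"] = _slerp(p["P8"], p["T8"], 0.5)
    for mid, out, one, five in [("FCz", "FT7", "FC1", "FC5"), ("FCz", "FT8", "FC2", "FC6"),
                                ("CPz", "TP7", "CP1", "CP5"), ("CPz", "TP8", "CP2", "CP6")]:
        p[one] = _slerp(p[mid], p[out], 0.25)
        p[five] = _slerp(p[mid], p[out], 0.75)
    return p


def standard_positions(
    ch_names: list[str] | None = None, head_radius_cm: float = HEAD_RADIUS_CM
) -> tuple[list[str], np.ndarray]:
    """2-D projected electrode coordinates in centimetres.

    Returns
    -------
    (ch_names, positions) where positions is (n_channels, 2); x to the
    subject's right, y toward the nose.
    """
    if ch_names is None:
        ch_names = list(DEFAULT_CHANNELS)
    sphere = _build_unit_sphere()
    missing = [c for c in ch_names if c not in sphere]
    if missing:
        raise KeyError(f"unknown electrode label(s): {missing}")
    out = np.zeros((len(ch_names), 2))
    for i, name in enumerate(ch_names):
        v = sphere[name]
        polar = np.arccos(np.clip(v[2], -1.0, 1.0))
        azim = np.arctan2(v[0], v[1])
        r2d = head_radius_cm * polar
        out[i] = [r2d * np.sin(azim), r2d * np.cos(azim)]
    return list(ch_names), out


def adjacency_matrix(positions: np.ndarray, threshold_cm: float = 6.0) -> np.ndarray:
    """Boolean neighbour matrix: channels closer than ``threshold_cm`` apart."""
    positions = np.asarray(positions, float)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = d < threshold_cm
    np.fill_diagonal(adj, False)
    return adj
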