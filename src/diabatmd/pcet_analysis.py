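"""Trajectory post-processing for proton-coupled electron transfer.

Proton-transfer coordinates (donor–H and acceptor–H distances), persistent
transfer-event detection with hysteresis, dipole-based LE/CT state
assignment, torsion-window conformer labels and ensemble delay statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .constants import ANGSTROM_PER_BOHR


@dataclass
class PTDefinition:
    label: str
    donor_atom_index: int
    hydrogen_atom_index: int
    acceptor_atom_index: int

    def __post_init__(self) -> None:
        idx = {self.donor_atom_index, self.hydrogen_atom_index,
               self.acceptor_atom_index}
        if len(idx) != 3:
            raise ValueError("PT definition needs three distinct atom indices")


@dataclass
class PTEvent:
    pt_label: str
    event_time: float  # fs
    direction: str  # {forward, reverse}


def pt_coordinates(frames, definitions) -> dict:
    """Per-definition (d_donor_H, d_acceptor_H) series in Å."""
    out = {}
    n_atoms = len(frames[0].symbols)
    for d in definitions:
        for idx in (d.donor_atom_index, d.hydrogen_atom_index, d.acceptor_atom_index):
            if not 0 <= idx < n_atoms:
                raise IndexError(f"PT definition {d.label}: atom index {idx} out of range")
        dd, da = [], []
        for f in frames:
            h = f.coords[d.hydrogen_atom_index]
            dd.append(np.linalg.norm(h - f.coords[d.donor_atom_index]))
            da.append(np.linalg.norm(h - f.coords[d.acceptor_atom_index]))
        out[d.label] = (np.array(dd) * ANGSTROM_PER_BOHR,
                        np.array(da) * ANGSTROM_PER_BOHR)
    return out


def detect_pt_events(d_donor_h: np.ndarray, d_acceptor_h: np.ndarray,
                     times_fs: np.ndarray, label: str = "PT",
                     persistence_frames: int = 50,
                     hysteresis: float = 0.1) -> list[PTEvent]:
    """Persistent distance-ordering swaps.

    A forward event fires at the first frame where d_donor_H - d_acceptor_H
    > hysteresis (Å) and the proton stays on the acceptor side (difference
    > 0) for `persistence_frames`; reverse events swap the roles.  Events
    alternate: no duplicate without an intervening opposite event.
    """
    diff = np.asarray(d_donor_h) - np.asarray(d_acceptor_h)
    n = len(diff)
    state = "acceptor" if diff[0] > 0 else "donor"  # which side holds the proton
    events: list[PTEvent] = []
    i = 0
    while i < n:
        if state == "donor" and diff[i] > hysteresis:
            window = diff[i: i + persistence_frames]
            if len(window) >= persistence_frames and np.all(window > 0):
                events.append(PTEvent(label, float(times_fs[i]), "forward"))
                state = "acceptor"
            else:
                # transient crossing: skip past it
                j = i
                while j < n and diff[j] > 0:
                    j += 1
                i = j
                continue
        elif state == "acceptor" and diff[i] < -hysteresis:
            window = diff[i: i + persistence_frames]
            if len(window) >= persistence_frames and np.all(window < 0):
                events.append(PTEvent(label, float(times_fs[i]), "reverse"))
                state = "donor"
            else:
                j = i
                while j < n and diff[j] < 0:
                    j += 1
                i = j
                continue
        i += 1
    return events


def dipole_state_series(frames, threshold: float,
                        smoothing_frames: int = 11) -> np.ndarray:
    """Per-frame {LE-like, CT-like} assignment from the median-filtered
    dipole magnitude; CT-like when |μ| > threshold."""
    mags = []
    for f in frames:
        if f.dipole_moment is None:
            raise ValueError("frame missing dipole moment")
        mags.append(np.linalg.norm(f.dipole_moment))
    mags = np.asarray(mags)
    k = min(smoothing_frames, len(mags))
    if k % 2 == 0:
        k -= 1
    if k >= 3:
        mags = medfilt(mags, kernel_size=k)
    return np.where(mags > threshold, "CT-like", "LE-like")


def ct_onset_time(frames, threshold: float, smoothing_frames: int = 11
                  ) -> float | None:
    """Time (fs) of the first CT-like frame, or None."""
    states = dipole_state_series(frames, threshold, smoothing_frames)
    idx = np.flatnonzero(states == "CT-like")
    if len(idx) == 0:
        return None
    return float(frames[int(idx[0])].time)


def dihedral_deg(p0, p1, p2, p3) -> float:
    """IUPAC signed dihedral in (-180, 180]; error for collinear atoms."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined dihedral: collinear atoms")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def conformer_classify(frames, torsion_atoms: tuple, windows: list) -> list[str]:
    """Per-frame conformer labels from a dihedral.

    `windows` is a list of (label, lo_deg, hi_deg) half-open intervals in
    [-180, 180); overlapping windows are rejected; gaps map to 'other'.
    """
    for i, (la, lo_a, hi_a) in enumerate(windows):
        if not (-180.0 <= lo_a < hi_a <= 180.0):
            raise ValueError(f"window {la} outside [-180, 180]")
        for lb, lo_b, hi_b in windows[i + 1:]:
            if lo_a < hi_b and lo_b < hi_a:
                raise ValueError(f"overlapping torsion windows {la} and {lb}")
    labels = []
    i0, i1, i2, i3 = torsion_atoms
    for f in frames:
        ang = dihedral_deg(f.coords[i0], f.coords[i1], f.coords[i2], f.coords[i3])
        lab = "other"
        for name, lo, hi in windows:
            if lo <= ang < hi:
                lab = name
                break
        labels.append(lab)
    return labels


def ensemble_summary(event_lists: list, reference_times: list) -> pd.DataFrame:
    """Delay statistics per PT label across trajectories.

    `event_lists[k]` are the PTEvents of trajectory k; delays are measured
    from `reference_times[k]` (e.g. the CT-onset time).  Also reports the
    per-ensemble transfer fraction (trajectories with >= 1 forward event).
    """
    if len(event_lists) == 0:
        raise ValueError("need at least one trajectory")
    rows = []
    labels = sorted({e.pt_label for evs in event_lists for e in evs})
    n_traj = len(event_lists)
    for lab in labels:
        delays = []
        for evs, t0 in zip(event_lists, reference_times):
            for e in evs:
                if e.pt_label == lab and e.direction == "forward" and t0 is not None:
                    delays.append(e.event_time - t0)
        if delays:
            rows.append({"pt_label": lab, "n_events": len(delays),
                         "mean_delay_fs": float(np.mean(delays)),
                         "median_delay_fs": float(np.median(delays)),
                         "min_delay_fs": float(np.min(delays)),
                         "max_delay_fs": float(np.max(delays))})
        else:
            rows.append({"pt_label": lab, "n_events": 0,
                         "mean_delay_fs": np.nan, "median_delay_fs": np.nan,
                         "min_delay_fs": np.nan, "max_delay_fs": np.nan})
    if not rows:
        rows.append({"pt_label": "none", "n_events": 0, "mean_delay_fs": np.nan,
                     "median_delay_fs": np.nan, "min_delay_fs": np.nan,
                     "max_delay_fs": np.nan})
    df = pd.DataFrame(rows)
    transferred = sum(1 for evs in event_lists
                      if any(e.direction == "forward" for e in evs))
    df.attrs["transfer_fraction"] = transferred / n_traj
    df.attrs["n_trajectories"] = n_traj
    return df
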