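"""End-to-end photoactivation protocol on the PCET toy.

Ground-state equilibration → sudden-switch excitation into the
charge-transfer (CT) diabatic state → CT-surface MD until the forward
proton transfer has persisted → back electron transfer (closed-shell SCF
from scratch at the final CT geometry) → ground-surface MD until the
reverse proton transfer.  Excited-state SCF failures after the forward
transfer end the CT segment there (failed segments are a first-class
outcome of ΔSCF dynamics, mirrored from real campaigns where a fraction
of trajectories is discarded); a failure before the transfer aborts the
cycle for that seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bomd import (MDConfig, MDState, maxwell_boltzmann_velocities, relax_geometry,
                   run_md)
from .fixtures import PCETToy
from .grassmann import ExtrapolationHistory
from .pcet_analysis import ct_onset_time, detect_pt_events, pt_coordinates

log = logging.getLogger("diabatmd")


@dataclass
class PCETCycleResult:
    gs_frames: list
    ct_frames: list
    back_frames: list
    forward_events: list
    reverse_events: list
    ct_onset_fs: float | None
    excitation_energy: float
    gs_dipole: float
    ct_dipole: float
    gs_epol: float
    ct_epol: float
    ct_failed_at_fs: float | None = None

    @property
    def forward_delay_fs(self) -> float | None:
        """Delay of the first forward PT after the CT onset."""
        if not self.forward_events or self.ct_onset_fs is None:
            return None
        return self.forward_events[0].event_time - self.ct_onset_fs

    @property
    def reverse_delay_fs(self) -> float | None:
        """Delay of the reverse PT after the back-electron-transfer start."""
        if not self.reverse_events:
            return None
        return self.reverse_events[0].event_time - self.back_frames[0].time


def _events(frames, toy, persistence, hysteresis):
    d = toy.pt_definitions[0]
    dd, da = pt_coordinates(frames, [d])[d.label]
    times = np.array([f.time for f in frames])
    return detect_pt_events(dd, da, times, d.label, persistence, hysteresis), dd, da


def _run_until_event(state, driver, toy, config, direction, max_steps,
                     chunk=40, persistence=50, hysteresis=0.1,
                     settle_steps=0, allow_fail_after_event=False):
    """Advance MD in chunks until a PT event of `direction` has persisted
    (plus optional settling), the step budget runs out, or the electronic
    state fails."""
    frames = []
    failed_at = None
    steps = 0
    done_at = None
    while steps < max_steps:
        n = min(chunk, max_steps - steps)
        cfg = MDConfig(**{**config.__dict__, "n_steps": n})
        try:
            new_frames, state = run_md(state, cfg, driver)
        except RuntimeError as err:
            if not frames:
                raise
            ev, dd, da = _events(frames, toy, persistence, hysteresis)
            if allow_fail_after_event and any(e.direction == direction for e in ev):
                failed_at = frames[-1].time
                log.warning("electronic failure after the %s transfer (%s); "
                            "ending segment at t=%.1f fs", direction, err, failed_at)
                break
            raise
        frames.extend(new_frames)
        steps += n
        ev, dd, da = _events(frames, toy, persistence, hysteresis)
        if any(e.direction == direction for e in ev):
            if done_at is None:
                done_at = steps
            if steps - done_at >= settle_steps:
                break
    return frames, state, failed_at


def run_pcet_cycle(toy: PCETToy, seed: int = 11,
                   temperature: float = 300.0, tau_ps: float = 0.1,
                   dt_fs: float = 0.5, n_equil: int = 300,
                   max_ct_steps: int = 600, max_back_steps: int = 1600,
                   settle_steps: int = 40,
                   persistence: int = 50, hysteresis: float = 0.1,
                   dscf_method: str = "imom") -> PCETCycleResult:
    """One full forward/backward PCET cycle on the toy; raises if the cycle
    cannot be completed for this seed."""
    gs_drv = toy.driver("ground")
    g0 = relax_geometry(gs_drv, toy.geometry, fmax=1e-4)
    rng = np.random.default_rng(seed)
    state = MDState(g0, maxwell_boltzmann_velocities(g0, temperature, rng), None,
                    ExtrapolationHistory(), rng)
    state.electronic = gs_drv.solve_ground(g0)
    state.history.push(state.electronic.density.d_alpha,
                       state.electronic.density.d_beta, g0)
    base = dict(dt=dt_fs, thermostat="bussi", temperature=temperature, tau=tau_ps,
                surface="ground", state_label="GS")
    gs_frames, state = run_md(state, MDConfig(**base, n_steps=n_equil), gs_drv)
    gs_dipole = float(np.linalg.norm(gs_frames[-1].dipole_moment))
    gs_epol = gs_frames[-1].energy_pol

    # sudden switch onto the CT diabatic surface, keeping the velocities
    ct_drv = toy.driver("deltascf", dscf_method=dscf_method)
    ct_state = MDState(state.geometry, state.velocities, None,
                       ExtrapolationHistory(), state.rng)
    ct_state.electronic = ct_drv.initial_electronic(state.geometry, ct_state)
    if not ct_state.electronic.converged or ct_state.electronic.collapsed:
        raise RuntimeError("CT preparation failed at the sudden switch")
    exc = ct_state.electronic.excitation_energy
    ct_state.history.push(ct_state.electronic.density.d_alpha,
                          ct_state.electronic.density.d_beta, state.geometry)
    ct_cfg = MDConfig(**{**base, "surface": "deltascf", "state_label": "CT",
                         "n_steps": 0})
    ct_frames, ct_state, ct_failed = _run_until_event(
        ct_state, ct_drv, toy, ct_cfg, "forward", max_ct_steps,
        persistence=persistence, hysteresis=hysteresis,
        settle_steps=settle_steps, allow_fail_after_event=True)
    fwd, dd, da = _events(ct_frames, toy, persistence, hysteresis)
    fwd = [e for e in fwd if e.direction == "forward"]
    if not fwd:
        raise RuntimeError("no forward proton transfer within the CT segment")
    ct_dipole = float(np.linalg.norm(ct_frames[0].dipole_moment))
    ct_epol = ct_frames[0].energy_pol
    onset = ct_onset_time(ct_frames, threshold=0.5 * (gs_dipole + ct_dipole))

    # back electron transfer: closed-shell Aufbau SCF from scratch
    back = gs_drv.solve_ground(ct_state.geometry)
    if not back.converged:
        raise RuntimeError("closed-shell SCF after back-electron transfer failed")
    back_state = MDState(ct_state.geometry, ct_state.velocities, back,
                         ExtrapolationHistory(), ct_state.rng)
    back_state.history.push(back.density.d_alpha, back.density.d_beta,
                            ct_state.geometry)
    back_cfg = MDConfig(**{**base, "state_label": "GS-back", "n_steps": 0})
    back_frames, back_state, _ = _run_until_event(
        back_state, gs_drv, toy, back_cfg, "reverse", max_back_steps,
        persistence=persistence, hysteresis=hysteresis)
    rev, _, _ = _events(back_frames, toy, persistence, hysteresis)
    rev = [e for e in rev if e.direction == "reverse"]
    if not rev:
        raise RuntimeError("no reverse proton transfer within the back segment")

    return PCETCycleResult(
        gs_frames=gs_frames, ct_frames=ct_frames, back_frames=back_frames,
        forward_events=fwd, reverse_events=rev, ct_onset_fs=onset,
        excitation_energy=exc, gs_dipole=gs_dipole, ct_dipole=ct_dipole,
        gs_epol=gs_epol, ct_epol=ct_epol, ct_failed_at_fs=ct_failed)
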