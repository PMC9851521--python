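"""Vicarious trial-and-error (VTE) detection.

A VTE event is the pause-and-look-around behaviour shown at decision
points: a frame whose speed is below ``v_threshold`` while its angular
speed exceeds ``theta_dot_threshold``.  Both thresholds are per-frame
quantities, so irregularly-timestamped trajectories are first resampled to
a uniform frame rate.  The VTE rate of a trial is the percentage of its
frames flagged; the per-state map averages, across trials, the flagged
fraction of the frames each trial spends at a node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from infonav.maze import MazeGraph
from infonav.trajectory import ContinuousTrajectory


@dataclass
class VTEConfig:
    """Thresholds and resampling settings for VTE detection.

    ``v_threshold`` is in distance units per frame, ``theta_dot_threshold``
    in degrees per frame; ``frame_rate`` (Hz) is the uniform rate frames
    are resampled to before thresholding.  ``exclude_states`` lists nodes
    (e.g. dead ends) omitted from the per-state map.
    """

    v_threshold: float = 1.0
    theta_dot_threshold: float = 10.0
    frame_rate: float = 10.0
    exclude_states: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.v_threshold <= 0 or self.theta_dot_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")


@dataclass
class Kinematics:
    """Uniformly sampled frames with per-frame speed and angular speed."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    speed: np.ndarray
    angular_speed: np.ndarray


def wrap_angle(delta: np.ndarray | float):
    """Wrap heading differences (degrees) to (-180, 180]."""
    wrapped = -((-np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def _is_uniform(t: np.ndarray, rate: float) -> bool:
    dt = np.diff(t)
    return bool(np.allclose(dt, 1.0 / rate, rtol=0, atol=1e-9))


def kinematics(traj: ContinuousTrajectory, cfg: VTEConfig) -> Kinematics:
    """Per-frame speed and angular speed at the target frame rate.

    Already-uniform trajectories pass through untouched; otherwise frames
    are linearly resampled (headings interpolated on the circle by the
    shortest arc).  The first frame's speed and angular speed are 0.
    """
    if len(traj.frames) < 2:
        raise ValueError("kinematics needs at least 2 frames")
    t, x, y, theta = traj.t, traj.frames[:, 1], traj.frames[:, 2], traj.theta
    if not _is_uniform(t, cfg.frame_rate):
        n = int(np.floor((t[-1] - t[0]) * cfg.frame_rate)) + 1
        tn = t[0] + np.arange(n) / cfg.frame_rate
        x = np.interp(tn, t, x)
        y = np.interp(tn, t, y)
        # unwrap so linear interpolation follows the shortest arc
        theta_u = np.concatenate([[theta[0]], theta[0] + np.cumsum(wrap_angle(np.diff(theta)))])
        theta = np.interp(tn, t, theta_u)
        t = tn
    speed = np.concatenate([[0.0], np.hypot(np.diff(x), np.diff(y))])
    angular = np.concatenate([[0.0], np.abs(wrap_angle(np.diff(theta)))])
    return Kinematics(t=t, x=x, y=y, theta=theta, speed=speed, angular_speed=angular)


def detect_vte_frames(kin: Kinematics, cfg: VTEConfig) -> np.ndarray:
    """Boolean flags: halted (speed < threshold) and sweeping
    (angular speed > threshold)."""
    return (kin.speed < cfg.v_threshold) & (kin.angular_speed > cfg.theta_dot_threshold)


def vte_rate(flags: Sequence[bool] | np.ndarray) -> float:
    """Percentage of flagged frames over the whole trial."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("cannot compute a VTE rate without frames")
    return float(100.0 * flags.mean())


def per_state_vte(
    trials: Iterable[ContinuousTrajectory],
    graph: MazeGraph,
    cfg: VTEConfig,
) -> dict[int, float]:
    """Mean per-state VTE rate across trials.

    For each trial, every (resampled) frame is assigned to its nearest
    node; the trial's contribution to a state is the flagged fraction of
    its frames at that state (x100).  States in ``cfg.exclude_states`` and
    states never visited are omitted.
    """
    from infonav.trajectory import assign_frames

    coords = graph.coord_array()
    ids = np.array(graph.node_ids)
    per_state: dict[int, list[float]] = {}
    excluded = set(cfg.exclude_states)
    for traj in trials:
        kin = kinematics(traj, cfg)
        flags = detect_vte_frames(kin, cfg)
        xy = np.column_stack([kin.x, kin.y])
        d2 = ((xy[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        nodes = ids[np.argmin(d2, axis=1)]
        for s in np.unique(nodes):
            if int(s) in excluded:
                continue
            at_s = nodes == s
            per_state.setdefault(int(s), []).append(100.0 * flags[at_s].mean())
    return {s: float(np.mean(vals)) for s, vals in sorted(per_state.items())}
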