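"""Synthetic multi-state benchmark systems with known important atoms.

A toy system mimics a macromolecule whose metastable states differ by the
displacement of a small, state-specific subset of atoms.  Atoms are placed
uniformly at random in a cubic box; each state displaces its own disjoint
set of "important" atoms, either linearly (one shared translation vector)
or nonlinearly (a chain of rotations about preceding atoms, emulating e.g.
a helix twist).  Synthetic frames are i.i.d. draws: the state's displaced
configuration plus per-coordinate uniform noise on *all* atoms, optionally
followed by a uniformly random rotation of the whole frame about the
origin — because only relative atomic positions carry meaning in real
systems, and alignment is deliberately not assumed.

The displaced-atom sets are the ground truth that benchmark scoring
compares importance profiles against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ToyConfig",
    "ToySystem",
    "ToyTrajectory",
    "generate_system",
    "generate_frames",
    "true_importance",
]


@dataclass(frozen=True)
class ToyConfig:
    """Parameters of a toy system.

    Defaults reproduce the standard benchmark setting: 100 atoms in a box
    spanning [-1, 1] per axis, three states with 10 displaced atoms each,
    displacement magnitude 0.1, uniform noise amplitude 0.01 and 1200
    frames per state.
    """

    n_atoms: int = 100
    box_half_width: float = 1.0
    n_states: int = 3
    n_important_per_state: int = 10
    displacement_magnitude: float = 0.1
    noise_amplitude: float = 0.01
    n_frames_per_state: int = 1200
    displacement_mode: str = "linear"
    rotate: bool = True
    seed: int = 0
    # nonlinear mode: rotation angle of atom k+1 about atom k is
    # nonlinear_angle * (state_index + 1), about ``nonlinear_axis``
    nonlinear_angle: float = np.pi / 4
    nonlinear_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_atoms < 1 or self.n_states < 1 or self.n_important_per_state < 1:
            raise ValueError("counts must be >= 1")
        if self.n_frames_per_state < 1:
            raise ValueError("n_frames_per_state must be >= 1")
        if self.box_half_width <= 0:
            raise ValueError("box_half_width must be > 0")
        if self.displacement_magnitude < 0 or self.noise_amplitude < 0:
            raise ValueError("lengths must be non-negative")
        if self.displacement_mode not in ("linear", "nonlinear"):
            raise ValueError(f"unknown displacement_mode {self.displacement_mode!r}")
        if self.n_states * self.n_important_per_state > self.n_atoms:
            raise ValueError(
                "infeasible config: n_states * n_important_per_state "
                f"({self.n_states * self.n_important_per_state}) exceeds "
                f"n_atoms ({self.n_atoms}); important sets must be disjoint"
            )


@dataclass
class ToySystem:
    """A generated system: equilibrium geometry, per-state displaced geometry
    and the disjoint important-atom sets that define the states."""

    equilibrium_coords: np.ndarray  # (n_atoms, 3)
    important_sets: list[np.ndarray]  # per state, sorted atom indices
    per_state_displaced_coords: np.ndarray  # (n_states, n_atoms, 3)
    config: ToyConfig


@dataclass
class ToyTrajectory:
    """Frames stacked over states with per-frame state labels."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    labels: np.ndarray  # (n_frames,) int state index
    system: ToySystem


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_system(config: ToyConfig) -> ToySystem:
    """Place atoms in the box and build each state's displaced configuration.

    Linear mode: all important atoms of a state share one displacement
    vector of norm ``displacement_magnitude`` whose direction is drawn per
    state.  Nonlinear mode: the first important atom of a state is
    translated with state-dependent direction; each subsequent important
    atom is rotated about the (displaced) position of the previous atom in
    that state, by an angle growing with the state index.
    """
    rng = np.random.default_rng(config.seed)
    b = config.box_half_width
    eq = rng.uniform(-b, b, size=(config.n_atoms, 3))

    n_imp = config.n_states * config.n_important_per_state
    chosen = rng.choice(config.n_atoms, size=n_imp, replace=False)
    important_sets = [
        np.sort(chosen[s * config.n_important_per_state : (s + 1) * config.n_important_per_state])
        for s in range(config.n_states)
    ]

    displaced = np.repeat(eq[None, :, :], config.n_states, axis=0)
    for s in range(config.n_states):
        idx = important_sets[s]
        direction = _random_unit_vector(rng)
        if config.displacement_mode == "linear":
            displaced[s, idx] = eq[idx] + config.displacement_magnitude * direction
        else:
            # chain: translate the first atom, rotate each subsequent atom
            # about the previous atom's new position in this state
            shift = config.displacement_magnitude * (s + 1) / config.n_states
            displaced[s, idx[0]] = eq[idx[0]] + shift * direction
            angle = config.nonlinear_angle * (s + 1)
            axis = np.asarray(config.nonlinear_axis, dtype=float)
            rot = Rotation.from_rotvec(angle * axis / np.linalg.norm(axis))
            for k in range(1, len(idx)):
                pivot = displaced[s, idx[k - 1]]
                displaced[s, idx[k]] = pivot + rot.apply(eq[idx[k]] - pivot)
    return ToySystem(eq, important_sets, displaced, config)


def generate_frames(system: ToySystem) -> ToyTrajectory:
    """Draw ``n_frames_per_state`` frames per state.

    Each frame is the state's displaced configuration plus independent
    uniform noise in [-noise_amplitude, +noise_amplitude] on every
    coordinate of every atom, then (if configured) a fresh uniformly random
    rotation about the origin.  Frames are independent draws; no temporal
    correlation is modelled.
    """
    cfg = system.config
    rng = np.random.default_rng(cfg.seed + 1)
    n_frames = cfg.n_states * cfg.n_frames_per_state
    coords = np.empty((n_frames, cfg.n_atoms, 3))
    labels = np.empty(n_frames, dtype=int)
    i = 0
    for s in range(cfg.n_states):
        base = system.per_state_displaced_coords[s]
        for _ in range(cfg.n_frames_per_state):
            frame = base + rng.uniform(-cfg.noise_amplitude, cfg.noise_amplitude, size=base.shape)
            if cfg.rotate:
                frame = frame @ Rotation.random(rng=rng).as_matrix().T
            coords[i] = frame
            labels[i] = s
            i += 1
    return ToyTrajectory(coords, labels, system)


def true_importance(system: ToySystem, state: int | None = None) -> np.ndarray:
    """Ground-truth per-atom importance ψ.

    Binary indicator over the displaced atoms of ``state`` (or the union
    over all states when omitted), ℓ2-normalized so that ψ·ψ = 1.
    """
    cfg = system.config
    if state is not None and not 0 <= state < cfg.n_states:
        raise ValueError(f"invalid state index {state}")
    psi = np.zeros(cfg.n_atoms)
    sets = system.important_sets if state is None else [system.important_sets[state]]
    for idx in sets:
        psi[idx] = 1.0
    return psi / np.linalg.norm(psi)
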