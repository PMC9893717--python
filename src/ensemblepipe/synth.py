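"""Synthetic rasters with planted ensembles and known ground truth.

The generator emulates the structure this pipeline is built to detect:
disjoint groups of neurons (ensembles) that coactivate during scheduled
epochs, the epochs following a repeating temporal sequence over the
ensemble labels, on top of independent Bernoulli background firing. Every
downstream stage (graph clustering, runs-test calibration, transition
graphs, recurrence analysis) can therefore be tested against a known truth
without any recorded data.

The four named presets encode qualitative contrasts between experimental
conditions of striatal microcircuits, as generator-planted properties:

* ``control_like`` -- balanced sequence with many distinct transitions,
  moderate background.
* ``decorticated_like`` -- near-isolated ensembles on a unidirectional
  ring with long silent gaps and the lowest background rate.
* ``parkinsonian_like`` -- fewest ensembles, one dominant recurring
  transition pair, regular epoch timing.
* ``dyskinetic_like`` -- the most ensembles, densest sequence, highest
  background rate.

Preset numbers are implementation constants chosen to plant those
contrasts at desk scale; they are not estimates of any recorded dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

from .raster import Raster

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_raster",
    "preset",
    "even_membership",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "control_like",
    "decorticated_like",
    "parkinsonian_like",
    "dyskinetic_like",
)


def even_membership(n_neurons: int, n_ensembles: int) -> Tuple[Tuple[int, ...], ...]:
    """Partition ``0..n_neurons-1`` into ``n_ensembles`` near-equal groups.

    When ``n_ensembles`` does not divide ``n_neurons``, the remainder
    neurons are left unassigned (background-only neurons).
    """
    size = n_neurons // n_ensembles
    if size < 1:
        raise ValueError("need at least one neuron per ensemble")
    return tuple(
        tuple(range(k * size, (k + 1) * size)) for k in range(n_ensembles)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic raster with planted ensembles.

    ``sequence`` lists ensemble labels in planted temporal order; it is
    concatenated cyclically until the recording ends, with a silent gap of
    ``gap_length`` frames between consecutive epochs (default: one epoch
    length). ``p_active_in_epoch`` is the per-frame firing probability of
    a member neuron during its ensemble's epoch; everywhere else every
    neuron fires with ``p_background`` per frame.
    """

    n_neurons: int
    n_frames: int
    fps: float
    n_ensembles: int
    membership: Tuple[Tuple[int, ...], ...]
    epoch_length: int
    sequence: Tuple[int, ...]
    p_active_in_epoch: float
    p_background: float
    seed: int
    gap_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_ensembles < 1:
            raise ValueError("n_ensembles must be >= 1")
        if self.epoch_length < 1:
            raise ValueError("epoch_length must be >= 1")
        if len(self.sequence) == 0:
            raise ValueError("sequence must be non-empty")
        for p, name in (
            (self.p_active_in_epoch, "p_active_in_epoch"),
            (self.p_background, "p_background"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if len(self.membership) != self.n_ensembles:
            raise ValueError(
                f"membership has {len(self.membership)} groups for "
                f"K={self.n_ensembles} ensembles"
            )
        seen: set[int] = set()
        for group in self.membership:
            for i in group:
                if not 0 <= int(i) < self.n_neurons:
                    raise ValueError(f"membership references unknown neuron {i}")
                if i in seen:
                    raise ValueError(f"neuron {i} appears in two ensembles")
                seen.add(i)
        for label in self.sequence:
            if not 0 <= int(label) < self.n_ensembles:
                raise ValueError(f"sequence references unknown ensemble {label}")
        object.__setattr__(
            self, "membership", tuple(tuple(int(i) for i in g) for g in self.membership)
        )
        object.__setattr__(self, "sequence", tuple(int(s) for s in self.sequence))

    @property
    def gap(self) -> int:
        return self.epoch_length if self.gap_length is None else self.gap_length

    def to_dict(self) -> dict:
        d = asdict(self)
        d["membership"] = [list(g) for g in self.membership]
        d["sequence"] = list(self.sequence)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["membership"] = tuple(tuple(g) for g in d["membership"])
        d["sequence"] = tuple(d["sequence"])
        return cls(**d)


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth accompanying a generated raster.

    ``labels[i]`` is the planted ensemble of neuron ``i`` (-1 for
    background-only neurons); ``epoch_schedule[t]`` the planted active
    ensemble at frame ``t`` (-1 when none); ``planted_transitions`` the
    ordered label pairs of consecutive realized epochs.
    """

    labels: np.ndarray
    epoch_schedule: np.ndarray
    planted_transitions: Tuple[Tuple[int, int], ...]

    @property
    def epoch_onsets(self) -> np.ndarray:
        """``(n_epochs, 2)`` array of (onset frame, ensemble label)."""
        sched = self.epoch_schedule
        onsets = []
        prev = -1
        for t, lab in enumerate(sched):
            if lab >= 0 and lab != prev:
                onsets.append((t, int(lab)))
            prev = lab
        return np.array(onsets, dtype=int).reshape(-1, 2)


def _build_schedule(config: SynthConfig) -> np.ndarray:
    """Per-frame planted ensemble label (-1 = silent gap)."""
    sched = np.full(config.n_frames, -1, dtype=int)
    pos = config.gap  # lead-in gap so the recording starts at baseline
    i = 0
    while pos < config.n_frames:
        label = config.sequence[i % len(config.sequence)]
        end = min(pos + config.epoch_length, config.n_frames)
        sched[pos:end] = label
        pos = end + config.gap
        i += 1
    return sched


def generate_raster(config: SynthConfig) -> Tuple[Raster, SynthTruth]:
    """Draw a raster from the planted-ensemble model, with its ground truth.

    Deterministic given ``config.seed`` (single RNG stream per call).
    """
    rng = np.random.default_rng(config.seed)
    n, f = config.n_neurons, config.n_frames
    matrix = (rng.random((n, f)) < config.p_background).astype(np.uint8)
    schedule = _build_schedule(config)
    # Overwrite member activity inside each scheduled epoch.
    for k, group in enumerate(config.membership):
        if not group:
            continue
        cols = np.flatnonzero(schedule == k)
        if cols.size == 0:
            continue
        rows = np.asarray(group, dtype=int)
        matrix[np.ix_(rows, cols)] = (
            rng.random((rows.size, cols.size)) < config.p_active_in_epoch
        ).astype(np.uint8)

    labels = np.full(n, -1, dtype=int)
    for k, group in enumerate(config.membership):
        labels[list(group)] = k

    # Realized epoch order -> planted transition pairs.
    order = []
    prev = -1
    in_epoch = False
    for lab in schedule:
        if lab >= 0 and not in_epoch:
            order.append(int(lab))
            in_epoch = True
        elif lab < 0:
            in_epoch = False
    transitions = tuple(zip(order[:-1], order[1:]))

    raster = Raster(matrix, fps=config.fps)
    return raster, SynthTruth(labels, schedule, transitions)


def preset(name: str, seed: int = 0) -> SynthConfig:
    """Named preset configurations encoding the condition-like contrasts."""
    if name == "control_like":
        # Balanced: each of 6 ensembles appears twice per pass, transitions
        # spread over many distinct ordered pairs.
        return SynthConfig(
            n_neurons=60,
            n_frames=3000,
            fps=4.0,
            n_ensembles=6,
            membership=even_membership(60, 6),
            epoch_length=12,
            gap_length=2,
            sequence=(0, 1, 2, 3, 4, 5, 0, 2, 4, 1, 3, 5),
            p_active_in_epoch=0.9,
            p_background=0.02,
            seed=seed,
        )
    if name == "decorticated_like":
        # Unidirectional ring of near-isolated ensembles: long silent gaps
        # between epochs, the lowest per-neuron background rate of the four
        # presets, large ensembles so the summed ensemble rate spreads over
        # many distinct levels (its states rarely recur within the fixed
        # recurrence radius).
        return SynthConfig(
            n_neurons=400,
            n_frames=3000,
            fps=4.0,
            n_ensembles=8,
            membership=even_membership(400, 8),
            epoch_length=12,
            gap_length=36,
            sequence=(0, 1, 2, 3, 4, 5, 6, 7),
            p_active_in_epoch=0.9,
            p_background=0.019,
            seed=seed,
        )
    if name == "parkinsonian_like":
        # Few ensembles, regular timing, one dominant ordered pair (0 -> 1
        # accounts for half of the within-sequence transitions).
        return SynthConfig(
            n_neurons=48,
            n_frames=3000,
            fps=4.0,
            n_ensembles=3,
            membership=even_membership(48, 3),
            epoch_length=12,
            gap_length=24,
            sequence=(0, 1, 0, 1, 0, 1, 0, 1, 2),
            p_active_in_epoch=0.9,
            p_background=0.02,
            seed=seed,
        )
    if name == "dyskinetic_like":
        # Most ensembles, densest epoch packing, highest per-neuron
        # background; small ensembles keep the summed rate in a narrow
        # band, so its states recur often.
        return SynthConfig(
            n_neurons=45,
            n_frames=3000,
            fps=4.0,
            n_ensembles=9,
            membership=even_membership(45, 9),
            epoch_length=12,
            gap_length=2,
            sequence=(0, 1, 2, 3, 4, 5, 6, 7, 8, 0, 3, 6, 1, 4, 7, 2, 5, 8),
            p_active_in_epoch=0.95,
            p_background=0.05,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
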