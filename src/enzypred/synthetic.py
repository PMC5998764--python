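"""Synthetic reaction sets and descriptor matrices with the statistical
structure the method assumes.

The method rests on one assumption: substrates of the same enzyme are
physico-chemically similar, so their descriptor vectors cluster.  The
generator reproduces exactly that geometry — each enzyme gets a center in
descriptor space (spread ``between_enzyme_sd``), each substrate sits at
its enzyme's center plus noise (spread ``within_enzyme_sd``) on the
signal columns, a fraction of substrates belong to a second enzyme and
average the two centers, a fraction of columns is pure noise, and
optional background molecules belong to no enzyme.  Positive pairs are
rare, as in real enzyme-substrate tables.  It does not attempt realistic
chemistry: values are Gaussian, not distributed like real descriptors,
and no valence or structural constraint exists.

Presets
-------
* ``separated`` — within/between spread ratio 10; clusters are clean and
  the pipeline should recover them (cross-validated AUC well above 0.5).
* ``hard`` — ratio 2; clusters overlap substantially.
* ``null`` — same geometry as ``separated`` but substrate identities in
  the reaction table are randomly permuted, destroying the link between
  geometry and labels; any pipeline should score at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .io_model import DescriptorMatrix, ReactionSet

__all__ = [
    "SimulationParams",
    "PRESETS",
    "preset_params",
    "simulate_dataset",
    "make_worked_example_fixture",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic generator (all sizes in molecules/columns).

    ``substrates_per_enzyme`` is an inclusive (low, high) range sampled
    uniformly per enzyme.  ``multi_enzyme_fraction`` is the probability a
    substrate is also assigned to a second random enzyme.  Background
    molecules get descriptor rows but no reactions; they serve as
    negative queries.
    """

    n_enzymes: int = 10
    substrates_per_enzyme: tuple[int, int] = (4, 6)
    descriptor_dim: int = 50
    within_enzyme_sd: float = 0.1
    between_enzyme_sd: float = 1.0
    multi_enzyme_fraction: float = 0.05
    n_background_molecules: int = 10
    noise_descriptor_fraction: float = 0.2
    shuffle_labels: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.within_enzyme_sd <= 0 or self.between_enzyme_sd <= 0:
            raise DomainError("standard deviations must be positive")
        for frac in (self.multi_enzyme_fraction, self.noise_descriptor_fraction):
            if not 0.0 <= frac <= 1.0:
                raise DomainError(f"fractions must lie in [0,1], got {frac}")
        if self.n_enzymes < 1 or self.descriptor_dim < 1:
            raise DomainError("need at least one enzyme and one descriptor")
        lo, hi = self.substrates_per_enzyme
        if not (1 <= lo <= hi):
            raise DomainError(
                f"substrates_per_enzyme range must satisfy 1 <= lo <= hi, got {lo, hi}"
            )
        if self.n_background_molecules < 0:
            raise DomainError("background count must be >= 0")


PRESETS: dict[str, SimulationParams] = {
    # within/between ratio 10: clean clusters the pipeline should recover
    "separated": SimulationParams(
        n_enzymes=10,
        substrates_per_enzyme=(5, 5),
        descriptor_dim=50,
        within_enzyme_sd=0.1,
        between_enzyme_sd=1.0,
    ),
    # ratio 2: heavy cluster overlap
    "hard": SimulationParams(
        n_enzymes=10,
        substrates_per_enzyme=(5, 5),
        descriptor_dim=50,
        within_enzyme_sd=0.5,
        between_enzyme_sd=1.0,
    ),
    # separated geometry, but reaction labels shuffled: chance performance
    "null": SimulationParams(
        n_enzymes=10,
        substrates_per_enzyme=(5, 5),
        descriptor_dim=50,
        within_enzyme_sd=0.1,
        between_enzyme_sd=1.0,
        shuffle_labels=True,
    ),
}


def preset_params(name: str, seed: int = 0) -> SimulationParams:
    if name not in PRESETS:
        raise DomainError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def simulate_dataset(
    P: SimulationParams,
) -> tuple[DescriptorMatrix, ReactionSet, dict[str, list[str]]]:
    """Draw a (descriptors, reactions, truth) triple from the parameters.

    ``truth`` maps every molecule id to the list of enzyme ids it truly
    belongs to (empty for background molecules) — the pre-shuffle
    assignment even under ``shuffle_labels``.  Fully reproducible from
    the seed.
    """
    P.validate()
    rng = np.random.default_rng(P.seed)
    n_signal = P.descriptor_dim - int(round(P.noise_descriptor_fraction * P.descriptor_dim))
    n_signal = max(n_signal, 1)

    enzymes = [f"E{i:03d}" for i in range(P.n_enzymes)]
    centers = rng.normal(0.0, P.between_enzyme_sd, size=(P.n_enzymes, n_signal))

    assignment: dict[str, list[str]] = {}
    lo, hi = P.substrates_per_enzyme
    counter = 0
    for ei, enzyme in enumerate(enzymes):
        n_sub = int(rng.integers(lo, hi + 1))
        for _ in range(n_sub):
            sid = f"S{counter:04d}"
            counter += 1
            owners = [enzyme]
            if P.n_enzymes > 1 and rng.random() < P.multi_enzyme_fraction:
                other = int(rng.integers(0, P.n_enzymes - 1))
                if other >= ei:
                    other += 1
                owners.append(enzymes[other])
            assignment[sid] = owners

    rows: dict[str, np.ndarray] = {}
    for sid, owners in assignment.items():
        center = centers[[enzymes.index(e) for e in owners]].mean(axis=0)
        signal = center + rng.normal(0.0, P.within_enzyme_sd, size=n_signal)
        noise = rng.normal(0.0, P.between_enzyme_sd, size=P.descriptor_dim - n_signal)
        rows[sid] = np.concatenate([signal, noise])

    for b in range(P.n_background_molecules):
        bid = f"B{b:04d}"
        rows[bid] = rng.normal(0.0, P.between_enzyme_sd, size=P.descriptor_dim)
        assignment[bid] = []

    names = [f"D{j:03d}" for j in range(n_signal)] + [
        f"N{j:03d}" for j in range(P.descriptor_dim - n_signal)
    ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    D = DescriptorMatrix(frame)

    substrate_ids = [m for m, owners in assignment.items() if owners]
    reacting = {s: list(assignment[s]) for s in substrate_ids}
    if P.shuffle_labels:
        permuted = list(rng.permutation(substrate_ids))
        reacting = {
            new: list(assignment[old]) for old, new in zip(substrate_ids, permuted)
        }
    pairs = [(e, s) for s, es in reacting.items() for e in es]
    R = ReactionSet.from_pairs(pairs)
    return D, R, assignment


def make_worked_example_fixture() -> list[list[float]]:
    """The four individual-score lists of the worked integration examples.

    Two queries against a two-substrate enzyme ({0,1} vs {0.5,0.5}) and
    two against a four-substrate enzyme ({0,1,1,1} vs {0,0.2,0.5,1}).
    """
    return [
        [0.0, 1.0],
        [0.5, 0.5],
        [0.0, 1.0, 1.0, 1.0],
        [0.0, 0.2, 0.5, 1.0],
    ]
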