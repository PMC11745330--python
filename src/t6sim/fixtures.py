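"""Deterministic toy populations for tests and examples.

Each fixture is reproducible from its ``(name, seed)`` pair alone; no data
files are involved.
"""

from __future__ import annotations

import numpy as np

from .cells import DEFAULT_BIRTH_LENGTH, Population
from .competition import CompetitionConfig, StrainSpec, seed_disc
from .firing import FiringRates

FIXTURE_NAMES = ("overlap-pair", "lattice-3x3", "fig-disc", "aimed-needle")


def make_fixture(name: str, seed: int = 0):
    """Build a named deterministic fixture.

    * ``overlap-pair`` -- two parallel rods overlapping by 0.2 um, for the
      two-body relaxation oracle.
    * ``lattice-3x3`` -- nine unit rods on a 3 um grid, all horizontal.
    * ``fig-disc`` -- the canonical 600-cell 500:90:10 disc at radius 50 um.
    * ``aimed-needle`` -- a two-cell arrangement plus an analytic needle
      (base, direction) aimed straight at the second cell's flank.
    """
    rng = np.random.default_rng(seed)
    if name == "overlap-pair":
        pop = Population(n_toxins=1)
        # centres 0.8 um apart side-by-side: capsule surfaces overlap by 0.2
        pop.add_cells([0, 0], np.array([[0.0, 0.0], [0.0, 0.8]]),
                      [0.0, 0.0], [DEFAULT_BIRTH_LENGTH] * 2)
        return pop
    if name == "lattice-3x3":
        pop = Population(n_toxins=1)
        xs, ys = np.meshgrid(np.arange(3) * 3.0, np.arange(3) * 3.0)
        pos = np.stack([xs.ravel(), ys.ravel()], axis=-1)
        pop.add_cells(np.zeros(9, dtype=int), pos, np.zeros(9),
                      np.full(9, DEFAULT_BIRTH_LENGTH))
        return pop
    if name == "fig-disc":
        cfg = CompetitionConfig(
            strains=(
                StrainSpec("attacker", 500, sensitivity=[0.0, 0.0], arsenal=[1.0, 0.0]),
                StrainSpec("susceptible", 90, sensitivity=[1.0, 1.0]),
                StrainSpec("mutant", 10, sensitivity=[0.0, 1.0]),
            ),
            rates=FiringRates(1.0, 2.0), seed=seed)
        return seed_disc(cfg, rng)
    if name == "aimed-needle":
        pop = Population(n_toxins=1)
        # firer at origin pointing +x; target parallel, 1.4 um above:
        # needle fired from the firer's top flank reaches the target's
        # lower surface after 0.4 um of its 0.5 um length
        pop.add_cells([0, 1], np.array([[0.0, 0.0], [0.0, 1.4]]),
                      [0.0, 0.0], [DEFAULT_BIRTH_LENGTH] * 2)
        needle = {
            "firer_idx": np.array([0]),
            "base": np.array([[0.0, 0.5]]),
            "direction": np.array([[0.0, 1.0]]),
            "expected_entry": 0.4,
        }
        return pop, needle
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
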