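"""Pair interactions of the nucleus model.

All non-bonded interactions are cut-and-shifted Lennard-Jones:

    U(r) = 4*eps*[(s/r)^12 - (s/r)^6] + E_cut        for r < r_c,  0 otherwise
    E_cut = -4*eps*[(s/r_c)^12 - (s/r_c)^6]

so the potential is continuous (zero) at the cutoff.  Attractive classes use
r_c = 2.0 sigma; purely repulsive classes cut at the minimum r_c = 2^(1/6)*s
(the WCA construction, for which E_cut = +eps).

Default pair classes (energies in k_B*T, lengths in sigma):

* nucleolar-nucleolar        eps = 1.8, s = sigma_p          (self-attraction)
* nucleolar-NAD chromatin    eps = 1.8, s = (sigma_p + 1)/2  (specific)
* nucleolar-non-NAD          eps = 1.0, s = (sigma_p + 1)/2  (non-specific)
* chromatin B-B, C-C         eps = 0.3, s = 1.0, r_c = 2.0   (weak compartment
  attraction, enough to segregate compartments qualitatively)
* all other chromatin pairs  purely repulsive WCA with s = 1.0

sigma_l for particle-chromatin contacts follows arithmetic mixing of the
particle diameter sigma_p and the bead diameter 1 sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations_with_replacement

import numpy as np

__all__ = ["PairPotential", "InteractionTable", "pair_energy", "pair_force"]

_MIN_RC = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class PairPotential:
    """One cut-and-shifted LJ pair class: (epsilon, sigma_l, r_cut)."""

    epsilon: float
    sigma: float
    r_cut: float

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.sigma <= 0:
            raise ValueError("epsilon must be >= 0 and sigma > 0")
        if self.r_cut <= self.sigma:
            raise ValueError("r_cut must exceed sigma")

    @property
    def e_cut(self) -> float:
        sr6 = (self.sigma / self.r_cut) ** 6
        return -4.0 * self.epsilon * (sr6 * sr6 - sr6)

    @classmethod
    def attractive(cls, epsilon: float, sigma: float, r_cut: float = 2.0) -> "PairPotential":
        return cls(epsilon=epsilon, sigma=sigma, r_cut=r_cut)

    @classmethod
    def repulsive(cls, sigma: float, epsilon: float = 1.0) -> "PairPotential":
        """WCA: LJ truncated at its minimum, shifted to zero there."""
        return cls(epsilon=epsilon, sigma=sigma, r_cut=_MIN_RC * sigma)

    def energy(self, r: float) -> float:
        return pair_energy(r, self)

    def force(self, r: float) -> float:
        return pair_force(r, self)


def pair_energy(r: float, pot: PairPotential) -> float:
    """Cut-and-shifted LJ energy at separation ``r`` (k_B*T); exactly zero for
    r >= r_cut.  Raises for non-positive separations."""
    if r <= 0:
        raise ValueError(f"pair separation must be positive, got {r!r}")
    if r >= pot.r_cut:
        return 0.0
    sr6 = (pot.sigma / r) ** 6
    return 4.0 * pot.epsilon * (sr6 * sr6 - sr6) + pot.e_cut


def pair_force(r: float, pot: PairPotential) -> float:
    """Magnitude of the radial force -dU/dr (positive = repulsive)."""
    if r <= 0:
        raise ValueError(f"pair separation must be positive, got {r!r}")
    if r >= pot.r_cut:
        return 0.0
    sr6 = (pot.sigma / r) ** 6
    return 24.0 * pot.epsilon * (2.0 * sr6 * sr6 - sr6) / r


_CHROM_TYPES = ("A", "B", "C")


@dataclass(frozen=True)
class InteractionTable:
    """All pair classes of the model plus bond / wall parameters.

    ``chromatin`` maps unordered type pairs ("AA", "AB", ...) to potentials.
    Bonds between consecutive beads of a chromosome are harmonic with rest
    length ``bond_length`` and stiffness ``bond_k`` (k_B*T/sigma^2), stiff
    enough to keep bond-length fluctuations below ~6%.  The confinement wall
    is a purely repulsive shifted LJ acting on the distance to the sphere
    surface.  Directly bonded pairs are excluded from non-bonded forces.
    """

    nuc_nuc: PairPotential
    nuc_nad: PairPotential
    nuc_nonnad: PairPotential
    chromatin: dict[str, PairPotential]
    bond_k: float = 300.0
    bond_length: float = 1.0
    wall_sigma: float = 0.5
    wall_epsilon: float = 1.0

    def __post_init__(self) -> None:
        for a, b in combinations_with_replacement(_CHROM_TYPES, 2):
            if a + b not in self.chromatin:
                raise ValueError(f"missing chromatin pair class {a+b}")

    @classmethod
    def for_topology(cls, topology, **kwargs) -> "InteractionTable":
        return cls.defaults(nucleolar_diameter=topology.nucleolar_diameter, **kwargs)

    @classmethod
    def defaults(
        cls,
        nucleolar_diameter: float = 0.5,
        eps_self: float = 1.8,
        eps_specific: float = 1.8,
        eps_nonspecific: float = 1.0,
        r_cut: float = 2.0,
        eps_compartment: float = 0.3,
        **kwargs,
    ) -> "InteractionTable":
        """Default table; ``eps_specific`` is the nucleolar-particle/NAD
        interaction strength swept in the interaction-strength experiments."""
        sp = nucleolar_diameter
        mix = 0.5 * (sp + 1.0)
        chromatin = {}
        for a, b in combinations_with_replacement(_CHROM_TYPES, 2):
            if a == b and a in ("B", "C"):
                chromatin[a + b] = PairPotential.attractive(eps_compartment, 1.0, r_cut)
            else:
                chromatin[a + b] = PairPotential.repulsive(1.0)
        return cls(
            nuc_nuc=PairPotential.attractive(eps_self, sp, r_cut),
            nuc_nad=PairPotential.attractive(eps_specific, mix, r_cut),
            nuc_nonnad=PairPotential.attractive(eps_nonspecific, mix, r_cut),
            chromatin=chromatin,
            **kwargs,
        )

    def relaxed(self) -> "InteractionTable":
        """Equilibration variant: every nucleolar epsilon set to 1.0 k_B*T so
        droplets do not nucleate while steric clashes anneal away."""
        return replace(
            self,
            nuc_nuc=replace(self.nuc_nuc, epsilon=1.0),
            nuc_nad=replace(self.nuc_nad, epsilon=1.0),
            nuc_nonnad=replace(self.nuc_nonnad, epsilon=1.0),
        )

    def chromatin_pair(self, type_a: str, type_b: str) -> PairPotential:
        key = "".join(sorted(type_a + type_b))
        return self.chromatin[key]

    def classify(self, code_i: int, code_j: int) -> PairPotential:
        """Potential for engine codes (0..5 chromatin = type + 3*NAD, 6 nucleolar)."""
        if code_i == 6 and code_j == 6:
            return self.nuc_nuc
        if code_i == 6 or code_j == 6:
            chrom_code = code_j if code_i == 6 else code_i
            return self.nuc_nad if chrom_code >= 3 else self.nuc_nonnad
        return self.chromatin_pair(_CHROM_TYPES[code_i % 3], _CHROM_TYPES[code_j % 3])

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """7x7 (eps, sigma, r_cut, e_cut) lookup matrices for the engine."""
        eps = np.zeros((7, 7))
        sig = np.ones((7, 7))
        rc = np.ones((7, 7))
        ec = np.zeros((7, 7))
        for i in range(7):
            for j in range(7):
                pot = self.classify(i, j)
                eps[i, j] = pot.epsilon
                sig[i, j] = pot.sigma
                rc[i, j] = pot.r_cut
                ec[i, j] = pot.e_cut
        return eps, sig, rc, ec

    @property
    def max_cutoff(self) -> float:
        pots = [self.nuc_nuc, self.nuc_nad, self.nuc_nonnad, *self.chromatin.values()]
        return max(p.r_cut for p in pots)
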