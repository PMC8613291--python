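"""Reduced <-> physical unit mapping for the nucleus model.

The simulation works in reduced units: the chromatin bead diameter sets the
length unit sigma, the thermal energy k_B*T sets the energy unit, and the
Brownian time tau_B (the time for a bead to diffuse its own diameter) sets
the time unit.  Mapping to physical units anchors sigma by equating the
confinement radius of the model (in sigma) with a typical nuclear radius
(in micrometres), and anchors tau_B through the Stokes-Einstein relation for
a sphere of diameter sigma in a medium of given viscosity.

The module also carries the analytic estimators used to size the nucleolar
subsystem: the number of coarse-grained nucleolar particles implied by a
protein concentration, and the particle diameter implied by a space-filling
model of the nucleolus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_J_PER_K",
    "UnitSystem",
    "ParticleEstimate",
    "length_unit_from_nucleus",
    "brownian_time",
    "particle_count_from_concentration",
    "droplet_radius_from_count",
    "particle_diameter_space_filling",
]

#: Boltzmann constant in J/K (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Avogadro constant in 1/mol.
AVOGADRO_PER_MOL = 6.02214076e23


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


def length_unit_from_nucleus(
    nucleus_radius_physical: float, nucleus_radius_reduced: float
) -> float:
    """Physical length per reduced length unit, in um per sigma.

    Obtained by equating the nuclear radius in physical units with the
    confinement radius of the model in sigma.  With the defaults (a 5 um
    nucleus confined at 19.7 sigma) this gives sigma = 0.254 um.
    """
    _require_positive(
        nucleus_radius_physical=nucleus_radius_physical,
        nucleus_radius_reduced=nucleus_radius_reduced,
    )
    return nucleus_radius_physical / nucleus_radius_reduced


def brownian_time(viscosity: float, length_unit: float, thermal_energy: float) -> float:
    """Brownian time tau_B = 30*pi*eta*sigma^3 / (k_B*T), in seconds.

    Parameters
    ----------
    viscosity:
        Dynamic viscosity of the medium in Pa*s (nucleoplasm ~1e-2 Pa*s).
    length_unit:
        The reduced length unit sigma expressed in metres.
    thermal_energy:
        k_B*T in joules at the physical reference temperature.

    The prefactor follows from matching the diffusion coefficient of a
    Stokes sphere of diameter sigma: D = k_B*T/(3*pi*eta*sigma), and defining
    tau_B as the time to diffuse sigma^2/(6D)*... collapsed into the single
    closed form 30*pi*eta*sigma^3/(k_B*T).
    """
    _require_positive(
        viscosity=viscosity, length_unit=length_unit, thermal_energy=thermal_energy
    )
    return 30.0 * math.pi * viscosity * length_unit**3 / thermal_energy


def particle_count_from_concentration(droplet_radius: float, concentration: float) -> int:
    """Number of particles in a droplet of radius ``droplet_radius`` (um) at
    molar concentration ``concentration`` (uM), rounded half-up.

    N = (4*pi/3) * N_A * R^3 * c with R in dm so that c in mol/L applies;
    here the arithmetic is done in SI and the result is dimensionless.
    """
    _require_positive(droplet_radius=droplet_radius, concentration=concentration)
    radius_m = droplet_radius * 1e-6
    conc_mol_per_m3 = concentration * 1e-6 * 1e3  # uM -> mol/m^3
    n = (4.0 * math.pi / 3.0) * AVOGADRO_PER_MOL * radius_m**3 * conc_mol_per_m3
    return int(math.floor(n + 0.5))


def droplet_radius_from_count(n_particles: float, concentration: float) -> float:
    """Inverse of :func:`particle_count_from_concentration`: droplet radius in
    um holding ``n_particles`` at ``concentration`` uM."""
    _require_positive(n_particles=n_particles, concentration=concentration)
    conc_mol_per_m3 = concentration * 1e-6 * 1e3
    radius_m = (3.0 * n_particles / (4.0 * math.pi * AVOGADRO_PER_MOL * conc_mol_per_m3)) ** (
        1.0 / 3.0
    )
    return radius_m * 1e6


def particle_diameter_space_filling(
    n_particles: float,
    nucleus_radius_reduced: float,
    nucleus_radius_physical: float,
    droplet_radius: float,
) -> float:
    """Nucleolar particle diameter sigma_p (in sigma) from a space-filling model.

    The model equates the total volume of ``n_particles`` spheres of diameter
    2^(1/6)*sigma_p (the equilibrium pair distance in the Lennard-Jones
    potential) with the volume fraction the nucleolus occupies in the nucleus:

        N_P * (2^(1/6)*sigma_p / 2)^3 / R_N^3 = (R_Nu / R_nucleus)^3

    with R_N the confinement radius in sigma and the right-hand side formed
    from physical radii (um).  Solved in closed form for sigma_p.
    """
    _require_positive(
        n_particles=n_particles,
        nucleus_radius_reduced=nucleus_radius_reduced,
        nucleus_radius_physical=nucleus_radius_physical,
        droplet_radius=droplet_radius,
    )
    ratio = droplet_radius / nucleus_radius_physical
    return (
        2.0
        / 2.0 ** (1.0 / 6.0)
        * nucleus_radius_reduced
        * ratio
        / n_particles ** (1.0 / 3.0)
    )


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and physical units.

    Attributes
    ----------
    length_unit:
        um per sigma.
    time_unit:
        seconds per tau_B.
    viscosity:
        Pa*s of the surrounding medium.
    thermal_energy:
        k_B*T in joules at the physical reference temperature.
    nucleus_radius_physical, nucleus_radius_reduced:
        The anchor pair defining the length unit.
    """

    length_unit: float
    time_unit: float
    viscosity: float
    thermal_energy: float
    nucleus_radius_physical: float
    nucleus_radius_reduced: float

    def __post_init__(self) -> None:
        _require_positive(
            length_unit=self.length_unit,
            time_unit=self.time_unit,
            viscosity=self.viscosity,
            thermal_energy=self.thermal_energy,
            nucleus_radius_physical=self.nucleus_radius_physical,
            nucleus_radius_reduced=self.nucleus_radius_reduced,
        )
        expected = self.nucleus_radius_physical / self.nucleus_radius_reduced
        if not math.isclose(self.length_unit, expected, rel_tol=1e-9):
            raise ValueError(
                "length_unit must equal nucleus_radius_physical / nucleus_radius_reduced "
                f"({expected!r}), got {self.length_unit!r}"
            )

    @classmethod
    def from_nucleus(
        cls,
        nucleus_radius_um: float = 5.0,
        confinement_radius_sigma: float = 19.7,
        viscosity_pa_s: float = 1e-2,
        reference_temperature_K: float = 310.0,
    ) -> "UnitSystem":
        """Build the default mapping: a 5 um nucleus at 19.7 sigma confinement,
        nucleoplasmic viscosity 1e-2 Pa*s, thermal energy at 310 K."""
        _require_positive(reference_temperature_K=reference_temperature_K)
        length_unit = length_unit_from_nucleus(nucleus_radius_um, confinement_radius_sigma)
        thermal_energy = BOLTZMANN_J_PER_K * reference_temperature_K
        time_unit = brownian_time(viscosity_pa_s, length_unit * 1e-6, thermal_energy)
        return cls(
            length_unit=length_unit,
            time_unit=time_unit,
            viscosity=viscosity_pa_s,
            thermal_energy=thermal_energy,
            nucleus_radius_physical=nucleus_radius_um,
            nucleus_radius_reduced=confinement_radius_sigma,
        )

    def to_physical_length(self, reduced: float) -> float:
        """Convert a length in sigma to um."""
        return reduced * self.length_unit

    def to_reduced_length(self, physical: float) -> float:
        """Convert a length in um to sigma."""
        return physical / self.length_unit

    def to_physical_time(self, reduced: float) -> float:
        """Convert a time in tau_B to seconds."""
        return reduced * self.time_unit

    def frame_interval_seconds(self, record_every: int, dt: float) -> float:
        """Physical spacing of recorded frames: record_every * dt * time_unit."""
        return record_every * dt * self.time_unit


@dataclass(frozen=True)
class ParticleEstimate:
    """Self-consistent sizing of the coarse-grained nucleolar subsystem."""

    n_particles: int
    droplet_radius: float  # um
    particle_diameter: float  # sigma
    concentration: float  # uM
    avogadro: float = AVOGADRO_PER_MOL

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        _require_positive(
            droplet_radius=self.droplet_radius,
            particle_diameter=self.particle_diameter,
            concentration=self.concentration,
        )

    @classmethod
    def from_count(
        cls,
        n_particles: int = 500,
        concentration: float = 1.0,
        nucleus_radius_reduced: float = 19.7,
        nucleus_radius_physical: float = 5.0,
    ) -> "ParticleEstimate":
        """Given a particle count and protein concentration, derive the droplet
        radius and the space-filling particle diameter."""
        radius = droplet_radius_from_count(n_particles, concentration)
        diameter = particle_diameter_space_filling(
            n_particles, nucleus_radius_reduced, nucleus_radius_physical, radius
        )
        return cls(
            n_particles=n_particles,
            droplet_radius=radius,
            particle_diameter=diameter,
            concentration=concentration,
        )
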