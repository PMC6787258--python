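"""Elastic-theory estimate of the protein coverage needed to form a tube.

Bending a flat bilayer into a cylinder of radius R costs, per unit area,
``f_tube(R) = k_c / (2 R^2)`` (Helfrich bending energy with bending
rigidity k_c and no spontaneous curvature or tension).  If each bound
protein contributes a curvature-dependent binding free energy dG_bind
(relative to the flat membrane) at its preferred radius R_bind, the areal
number density needed to pay the bending cost is

    rho = f_tube(R_bind) / |dG_bind|

and the corresponding area claimed per protein is 1/rho.  All energies are
in k_BT, so temperature never enters explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["TubeCoverage", "tube_energy_density", "required_density"]


@dataclass(frozen=True)
class TubeCoverage:
    """Inputs and results of the tube-coverage estimate."""

    kc: float  # bending rigidity, k_BT
    R_bind: float  # preferred binding radius of curvature, nm
    dG_bind: float  # binding free energy, k_BT (negative = favourable)
    f_tube: float  # elastic energy per area, k_BT nm^-2
    rho: float  # required protein number density, nm^-2
    area_per_protein: float  # nm^2

    def as_dict(self) -> dict:
        return {
            "kc_kBT": self.kc,
            "R_bind_nm": self.R_bind,
            "dG_bind_kBT": self.dG_bind,
            "f_tube_kBT_per_nm2": self.f_tube,
            "rho_per_nm2": self.rho,
            "area_per_protein_nm2": self.area_per_protein,
        }


def tube_energy_density(kc: float, R: float) -> float:
    """Elastic energy cost per unit area of a tube of radius R: kc/(2 R^2)."""
    if kc <= 0 or R <= 0:
        raise DomainError("bending rigidity and radius must both be positive")
    return kc / (2.0 * R**2)


def required_density(kc: float, R_bind: float, dG_bind: float) -> TubeCoverage:
    """Protein number density per area required to stabilize a tube.

    ``dG_bind`` must be nonzero; a positive (unfavourable) value triggers a
    warning since the coverage estimate is then physically meaningless.
    """
    if dG_bind == 0:
        raise DomainError(
            "dG_bind = 0: a protein with no curvature preference cannot pay "
            "the bending cost, the required density diverges"
        )
    if dG_bind > 0:
        warnings.warn(
            "dG_bind > 0 (binding to curvature is unfavourable); the coverage "
            "estimate is not meaningful",
            stacklevel=2,
        )
    f = tube_energy_density(kc, R_bind)
    rho = f / abs(dG_bind)
    return TubeCoverage(
        kc=kc,
        R_bind=R_bind,
        dG_bind=dG_bind,
        f_tube=f,
        rho=rho,
        area_per_protein=1.0 / rho,
    )
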