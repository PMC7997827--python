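"""Pathway stoichiometry with automatic elemental balancing.

Every metabolic pathway of the process model is written as one generalized
reaction of the carbon substrate with oxygen and a nitrogen source yielding
biomass, carbon dioxide, water and (optionally) a product:

    CxHyOz + nu1 O2 + nu2 HgOhNi -> nu3 CaHbOcNd + nu4 CO2 + nu5 H2O (+ nu6 P)

Coefficients that the user leaves free are solved from the four elemental
balances (C, H, O, N); fixed coefficients (e.g. a biomass yield chosen as a
degree of freedom) are honoured.  Mass yields Y_i/S follow from the molar
coefficients as Y_i/S = nu_i * MW_i / MW_S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from mdoe.errors import StoichiometryError

ELEMENTS = ("C", "H", "O", "N")

#: Standard atomic weights, g/mol (IUPAC 2021, abridged).
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

#: Roles on the reactant side of the generalized pathway equation.
REACTANT_ROLES = frozenset({"O2", "N-source", "cosubstrate"})
#: Roles on the product side.
PRODUCT_ROLES = frozenset({"biomass", "CO2", "H2O", "product"})


@dataclass(frozen=True)
class ElementalSpecies:
    """A chemical species given by its C/H/O/N composition.

    Non-integer element counts are allowed so that C-molar biomass formulas
    such as CH1.8O0.5N0.2 can be used directly.
    """

    name: str
    formula: Mapping[str, float]

    def __post_init__(self):
        unknown = set(self.formula) - set(ELEMENTS)
        if unknown:
            raise StoichiometryError(
                f"species {self.name!r} uses unsupported elements {sorted(unknown)}"
            )
        if any(v < 0 for v in self.formula.values()):
            raise StoichiometryError(f"species {self.name!r} has negative element counts")
        mw = float(sum(ATOMIC_MASS[e] * n for e, n in self.formula.items()))
        object.__setattr__(self, "_mw", mw)
        if mw <= 0:
            raise StoichiometryError(f"species {self.name!r} has non-positive weight")

    @property
    def molecular_weight(self) -> float:
        """Molecular (or C-molar) weight in g/mol, derived from the formula."""
        return self._mw

    def atoms(self, element: str) -> float:
        return float(self.formula.get(element, 0.0))


# common species used by the bundled reference model
GLUCOSE = ElementalSpecies("Glc", {"C": 6, "H": 12, "O": 6})
ETHANOL = ElementalSpecies("EtOH", {"C": 2, "H": 6, "O": 1})
OXYGEN = ElementalSpecies("O2", {"O": 2})
CO2 = ElementalSpecies("CO2", {"C": 1, "O": 2})
WATER = ElementalSpecies("H2O", {"H": 2, "O": 1})
AMMONIA = ElementalSpecies("N", {"H": 3, "N": 1})
BIOMASS = ElementalSpecies("X", {"C": 1, "H": 1.8, "O": 0.5, "N": 0.2})
EAA = ElementalSpecies("EAA", {"C": 6, "H": 10, "O": 3})
E3HB = ElementalSpecies("E3HB", {"C": 6, "H": 12, "O": 3})


@dataclass(frozen=True)
class PathwayStoichiometry:
    """One metabolic pathway: substrate, co-substrates/products and coefficients.

    Parameters
    ----------
    name:
        Pathway identifier.
    substrate:
        The rate-limiting substrate; its coefficient is 1 by definition.
    species:
        ``(species, role)`` pairs; roles in :data:`REACTANT_ROLES` sit on the
        left-hand side, roles in :data:`PRODUCT_ROLES` on the right.
    nu:
        Molar coefficient per species name (mol per mol substrate).  ``None``
        marks a coefficient to be solved by :func:`balance_pathway`.  Negative
        values move a species to the opposite side (e.g. water consumed by a
        reduction).
    """

    name: str
    substrate: ElementalSpecies
    species: tuple[tuple[ElementalSpecies, str], ...]
    nu: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        for sp, role in self.species:
            if role not in REACTANT_ROLES and role not in PRODUCT_ROLES:
                raise StoichiometryError(f"unknown role {role!r} for species {sp.name!r}")
        names = [sp.name for sp, _ in self.species]
        if len(names) != len(set(names)):
            raise StoichiometryError(f"pathway {self.name!r} lists a species twice")

    def signed_coefficient(self, name: str) -> float:
        """Coefficient with product-side positive sign convention."""
        for sp, role in self.species:
            if sp.name == name:
                v = self.nu.get(name)
                if v is None:
                    raise StoichiometryError(f"coefficient for {name!r} is unsolved")
                return v if role in PRODUCT_ROLES else -v
        raise KeyError(name)

    @property
    def is_balanced(self) -> bool:
        try:
            check_closure(self)
        except StoichiometryError:
            return False
        return True

    @property
    def yields(self) -> dict[str, float]:
        """Mass yields Y_i/S in g/g substrate for every species."""
        mws = self.substrate.molecular_weight
        out = {}
        for sp, _role in self.species:
            v = self.nu.get(sp.name)
            if v is None:
                raise StoichiometryError(f"coefficient for {sp.name!r} is unsolved")
            out[sp.name] = v * sp.molecular_weight / mws
        return out


def elemental_residual(p: PathwayStoichiometry) -> dict[str, float]:
    """Per-element imbalance: product atoms minus reactant atoms (incl. substrate)."""
    res = {}
    for e in ELEMENTS:
        total = -p.substrate.atoms(e)
        for sp, role in p.species:
            v = p.nu.get(sp.name)
            if v is None:
                raise StoichiometryError(f"coefficient for {sp.name!r} is unsolved")
            sign = 1.0 if role in PRODUCT_ROLES else -1.0
            total += sign * v * sp.atoms(e)
        res[e] = total
    return res


def check_closure(p: PathwayStoichiometry, tol: float = 1e-9) -> None:
    """Raise :class:`StoichiometryError` naming the worst element if unbalanced."""
    res = elemental_residual(p)
    worst = max(res, key=lambda e: abs(res[e]))
    if abs(res[worst]) > tol:
        raise StoichiometryError(
            f"pathway {p.name!r} does not conserve {worst}: residual {res[worst]:.3e}",
            element=worst,
        )


def balance_pathway(p: PathwayStoichiometry) -> PathwayStoichiometry:
    """Solve the free coefficients of a pathway from the C/H/O/N balances.

    Coefficients given as ``None`` in ``p.nu`` are unknowns; all others are
    kept fixed.  The linear system has one equation per element that appears
    anywhere in the reaction.  An under-determined system (more unknowns than
    independent balances) or an inconsistent one raises
    :class:`StoichiometryError` naming the offending element.
    """
    free = [name for name, v in p.nu.items() if v is None]
    known_species = {sp.name for sp, _ in p.species}
    missing = set(free) - known_species
    if missing:
        raise StoichiometryError(f"free coefficients {sorted(missing)} are not pathway species")

    # elements that actually occur anywhere in the reaction
    active = [
        e
        for e in ELEMENTS
        if p.substrate.atoms(e) != 0 or any(sp.atoms(e) != 0 for sp, _ in p.species)
    ]

    sign = {sp.name: (1.0 if role in PRODUCT_ROLES else -1.0) for sp, role in p.species}
    by_name = {sp.name: sp for sp, _ in p.species}

    a = np.zeros((len(active), len(free)))
    b = np.zeros(len(active))
    for row, e in enumerate(active):
        b[row] = p.substrate.atoms(e)
        for name, v in p.nu.items():
            if v is not None:
                b[row] -= sign[name] * v * by_name[name].atoms(e)
        for col, name in enumerate(free):
            a[row, col] = sign[name] * by_name[name].atoms(e)

    if free:
        if np.linalg.matrix_rank(a) < len(free):
            raise StoichiometryError(
                f"pathway {p.name!r}: elemental balances do not determine "
                f"coefficients {free} (under-determined system)"
            )
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        nu = dict(p.nu)
        nu.update({name: float(v) for name, v in zip(free, sol)})
        balanced = replace(p, nu=nu)
    else:
        balanced = p

    check_closure(balanced)
    return balanced
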