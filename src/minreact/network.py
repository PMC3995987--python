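"""Stoichiometric network data model.

A metabolic network is the sparse stoichiometric matrix S (N metabolites x
M reactions) together with flux bounds, reversibility flags, and the two
designations the minimal-reaction-set problem needs: exactly one biomass
reaction (the cellular objective) and a set of uptake reactions whose upper
bounds encode the medium. Extracellular/boundary metabolites are tracked but
excluded from the steady-state mass balance, following the usual boundary
convention of constraint-based modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxVector",
    "ValidationError",
    "DEFAULT_FLUX_BOUND",
    "MASS_BALANCE_TOL",
]

#: Default magnitude used when a bound is unspecified (mmol/gDW/h).
DEFAULT_FLUX_BOUND = 1000.0

#: Componentwise tolerance on |S.v| for a flux vector to count as balanced.
MASS_BALANCE_TOL = 1e-6


class ValidationError(ValueError):
    """A network violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_extracellular: bool = False


@dataclass(frozen=True)
class Reaction:
    """One reaction column: stoichiometry maps metabolite id -> signed
    coefficient (negative = consumed, positive = produced)."""

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    lb: float | None = None
    ub: float | None = None
    is_uptake: bool = False
    is_biomass: bool = False

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        lb = self.lb if self.lb is not None else (-DEFAULT_FLUX_BOUND if self.reversible else 0.0)
        ub = self.ub if self.ub is not None else DEFAULT_FLUX_BOUND
        if lb > ub:
            raise ValidationError(f"reaction {self.id!r}: lb {lb} > ub {ub}")
        if not self.reversible and lb < 0:
            raise ValidationError(f"reaction {self.id!r}: irreversible with lb {lb} < 0")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reactants(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass(frozen=True)
class FluxVector:
    """A steady-state flux assignment, reaction id -> flux."""

    values: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.values.get(rid, default)

    def support(self, tol: float = 1e-9) -> frozenset[str]:
        return frozenset(r for r, v in self.values.items() if abs(v) > tol)


class MetabolicNetwork:
    """Ordered collection of metabolites and reactions with a biomass target.

    Parameters
    ----------
    metabolites, reactions:
        Input order is preserved; it is the deterministic tie-break used by
        depth assignment, grouping and knockout selection.
    biomass_target:
        Minimum biomass flux (g/gDW/h) a reaction subset must sustain.
    uptake_limits:
        Optional per-uptake override of the maximum uptake rate; applied as
        the reaction's upper bound.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_target: float = 1.0,
        uptake_limits: Mapping[str, float] | None = None,
    ):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.biomass_target = float(biomass_target)
        self.uptake_limits: dict[str, float] = dict(uptake_limits or {})
        self._validate()
        if self.uptake_limits:
            self.reactions = [
                replace(r, ub=self.uptake_limits[r.id]) if r.id in self.uptake_limits else r
                for r in self.reactions
            ]
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        met_ids = seen
        seen = set()
        n_biomass = 0
        for r in self.reactions:
            if r.id in seen:
                raise ValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            for mid in r.stoichiometry:
                if mid not in met_ids:
                    raise ValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
            n_biomass += r.is_biomass
        if n_biomass != 1:
            raise ValidationError(f"expected exactly one biomass reaction, found {n_biomass}")
        if self.biomass_target <= 0:
            raise ValidationError("biomass_target must be > 0")
        for rid in self.uptake_limits:
            if rid not in seen:
                raise ValidationError(f"uptake limit for unknown reaction {rid!r}")

    # -- accessors ----------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def biomass_reaction(self) -> Reaction:
        return next(r for r in self.reactions if r.is_biomass)

    @property
    def uptake_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_uptake]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def reaction_position(self, rid: str) -> int:
        return self._rxn_index[rid]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    # -- matrices -----------------------------------------------------------
    def stoichiometric_matrix(self, internal_only: bool = False) -> np.ndarray:
        """Dense S (N x M); with ``internal_only`` the boundary rows are
        dropped — that submatrix defines the steady-state constraint."""
        mets = [m for m in self.metabolites if not (internal_only and m.is_extracellular)]
        idx = {m.id: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                if mid in idx:
                    S[idx[mid], j] = coef
        return S

    def mass_balance_residual(self, flux: FluxVector) -> float:
        """max_i |sum_j S_ij v_j| over internal metabolites."""
        S = self.stoichiometric_matrix(internal_only=True)
        v = np.array([flux.get(r.id) for r in self.reactions])
        if S.size == 0:
            return 0.0
        return float(np.max(np.abs(S @ v)))

    def subnetwork(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        """Restriction to the given reactions (and metabolites they touch)."""
        keep = set(reaction_ids)
        rxns = [r for r in self.reactions if r.id in keep]
        used = {mid for r in rxns for mid in r.stoichiometry}
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicNetwork(mets, rxns, biomass_target=self.biomass_target)

    def __repr__(self) -> str:
        return (
            f"MetabolicNetwork({self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions, biomass_target={self.biomass_target})"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.biomass_target == other.biomass_target
        )
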