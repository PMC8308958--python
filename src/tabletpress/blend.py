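"""Lot-aware powder blend compositions.

A blend is described by mass fractions keyed by ``(material, lot)``. The
material name selects the physical property set (densities, compaction
coefficients); the lot label is pure provenance and survives every mixing
operation, which is what makes per-tablet tracking and tracing possible:
two deliveries of the same grade stay distinguishable all the way from the
hopper to the finished tablet record.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Iterable, Mapping, Tuple

__all__ = ["BlendKey", "BlendComposition", "CompositionError"]

BlendKey = Tuple[str, str]

#: largest tolerated deviation of the fraction sum from one on input
_SUM_TOL = 1e-9


class CompositionError(ValueError):
    """Raised for non-normalised, negative or otherwise invalid fractions."""


class BlendComposition:
    """Immutable mass-fraction vector of a powder blend.

    Parameters
    ----------
    fractions:
        Mapping ``(material, lot) -> mass fraction``. Fractions must be
        non-negative and sum to one within ``1e-9``; the stored values are
        rescaled so the sum is exactly one, which keeps long mixing chains
        from accumulating drift.
    """

    __slots__ = ("_fractions",)

    def __init__(self, fractions: Mapping[BlendKey, float]):
        if not fractions:
            raise CompositionError("a blend needs at least one component")
        total = 0.0
        clean: dict[BlendKey, float] = {}
        for key, x in fractions.items():
            mat, lot = key
            if not (isinstance(mat, str) and isinstance(lot, str)):
                raise CompositionError(f"blend key must be (material, lot) strings, got {key!r}")
            if x < 0.0:
                raise CompositionError(f"negative mass fraction {x!r} for {key}")
            if x > 0.0:
                clean[key] = float(x)
            total += float(x)
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(f"mass fractions must sum to 1, got {total!r}")
        if not clean:
            raise CompositionError("all mass fractions are zero")
        self._fractions = MappingProxyType({k: v / total for k, v in clean.items()})

    # -- constructors ------------------------------------------------------

    @classmethod
    def single(cls, material: str, lot: str = "default") -> "BlendComposition":
        """Pure single-component blend."""
        return cls({(material, lot): 1.0})

    @classmethod
    def from_masses(cls, masses: Mapping[BlendKey, float]) -> "BlendComposition":
        """Build from absolute masses (g); fractions are masses / total."""
        total = sum(masses.values())
        if total <= 0.0:
            raise CompositionError(f"total mass must be positive, got {total!r}")
        return cls({k: m / total for k, m in masses.items() if m != 0.0})

    @classmethod
    def mix(cls, parcels: Iterable[tuple["BlendComposition", float]]) -> "BlendComposition":
        """Mass-weighted mixture of ``(composition, mass)`` parcels."""
        masses: dict[BlendKey, float] = {}
        for comp, mass in parcels:
            if mass < 0.0:
                raise CompositionError(f"parcel mass must be non-negative, got {mass!r}")
            for key, x in comp.items():
                masses[key] = masses.get(key, 0.0) + x * mass
        return cls.from_masses(masses)

    # -- accessors ---------------------------------------------------------

    @property
    def fractions(self) -> Mapping[BlendKey, float]:
        return self._fractions

    def items(self):
        return self._fractions.items()

    def keys(self):
        return self._fractions.keys()

    def __iter__(self):
        return iter(self._fractions)

    def __len__(self) -> int:
        return len(self._fractions)

    def __getitem__(self, key: BlendKey) -> float:
        return self._fractions.get(key, 0.0)

    def by_material(self) -> dict[str, float]:
        """Mass fractions aggregated over lots."""
        agg: dict[str, float] = {}
        for (mat, _), x in self._fractions.items():
            agg[mat] = agg.get(mat, 0.0) + x
        return agg

    def fraction_of(self, material: str) -> float:
        """Total mass fraction of one material, all lots combined."""
        return sum(x for (mat, _), x in self._fractions.items() if mat == material)

    def materials(self) -> set[str]:
        return {mat for mat, _ in self._fractions}

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, BlendComposition):
            return NotImplemented
        return dict(self._fractions) == dict(other._fractions)

    def __hash__(self) -> int:
        return hash(frozenset(self._fractions.items()))

    def __repr__(self) -> str:
        body = ", ".join(f"{mat}/{lot}={x:.6g}" for (mat, lot), x in sorted(self._fractions.items()))
        return f"BlendComposition({body})"
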