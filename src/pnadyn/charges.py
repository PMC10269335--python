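"""Deterministic partial-charge edits for substituted PNA residues.

When a hydrogen on the backbone gamma-carbon is replaced by a substituent
linkage, CHARMM practice folds the displaced hydrogen's +0.09e partial charge
onto the carbon it left (so a gamma-carbon at -0.02e becomes +0.07e), and the
residue is then returned to its target net charge by adjusting a single
designated atom (for the miniPEG-modified residue, N2' absorbs -0.03e,
becoming -0.36e).  Both edits conserve or restore the residue's net charge
exactly and are idempotent in the obvious sense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ChargeSet",
    "net_charge",
    "aggregate_hydrogen_charge",
    "repair_neutrality",
]


@dataclass(frozen=True)
class ChargeSet:
    """Ordered per-atom partial charges (elementary-charge units) for a group."""

    entries: dict[str, float] = field(default_factory=dict)
    group_id: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, q in dict(self.entries).items():
            if not str(name).strip():
                raise ValueError("blank atom name in charge set")
            q = float(q)
            if not math.isfinite(q):
                raise ValueError(f"non-finite charge for atom {name!r}")
            clean[str(name)] = q
        object.__setattr__(self, "entries", clean)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, atom_name: str) -> float:
        return self.entries[atom_name]

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.entries


def net_charge(charge_set: ChargeSet) -> float:
    """Exact sum of the partial charges (e); 0.0 for an empty set."""
    return math.fsum(charge_set.entries.values())


def _require(charge_set: ChargeSet, atom_name: str) -> None:
    if atom_name not in charge_set.entries:
        raise ValueError(
            f"atom {atom_name!r} not present in charge set {charge_set.group_id!r}"
        )


def aggregate_hydrogen_charge(charge_set: ChargeSet, hydrogen: str,
                              carbon: str) -> ChargeSet:
    """Fold a substituted hydrogen's charge onto its carbon.

    The hydrogen's entry is removed, the carbon's charge is incremented by the
    removed charge, and every other entry (and the net charge) is untouched.
    """
    _require(charge_set, hydrogen)
    _require(charge_set, carbon)
    entries = dict(charge_set.entries)
    q_h = entries.pop(hydrogen)
    entries[carbon] = entries[carbon] + q_h
    return ChargeSet(entries=entries, group_id=charge_set.group_id)


def repair_neutrality(charge_set: ChargeSet, atom: str,
                      target_net: float = 0.0) -> ChargeSet:
    """Adjust one designated atom so the set's net charge equals ``target_net``.

    The named atom's charge changes by ``target_net - net_charge(set)``; all
    other entries are untouched.  Applying the repair twice is a no-op.
    """
    _require(charge_set, atom)
    entries = dict(charge_set.entries)
    shortfall = target_net - net_charge(charge_set)
    entries[atom] = entries[atom] + shortfall
    return ChargeSet(entries=entries, group_id=charge_set.group_id)
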