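"""Zinc-arginine interaction index (modified FIC index on Young's moduli).

The fractional inhibitory concentration (FIC) index classifies how two
antimicrobials interact when combined.  Here the MICs are replaced by the
Young's moduli of treated biofilms: the combination (DZA) modulus is
referenced against each single-treatment modulus,

    IAI_Arg = E_DZA / E_Arg,   IAI_Zn = E_DZA / E_Zn,
    IAI     = IAI_Arg + IAI_Zn,

and the sum is classified: IAI ≤ 0.5 synergism, 0.5 < IAI < 4 additive,
IAI ≥ 4 antagonism.  The printed classification rule assigns IAI = 4 to
both the additive and the antagonism class; this implementation resolves
the overlap to antagonism, where the inequality is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ModulusTable
from .errors import DomainError, PairingError

__all__ = [
    "SYNERGISM_CUTOFF",
    "ANTAGONISM_CUTOFF",
    "InteractionResult",
    "classify_interaction",
    "interaction_index",
    "replicate_interaction_summary",
    "modulus_difference_and_ratio",
    "replicate_difference_ratio_summary",
]

SYNERGISM_CUTOFF = 0.5
ANTAGONISM_CUTOFF = 4.0

# Group labels expected by the replicate-level summaries.
GROUP_DZA = "dza"
GROUP_ARG = "arginine"
GROUP_ZN = "zinc"


@dataclass
class InteractionResult:
    """Interaction index with its two components and classification."""

    iai_arg: float
    iai_zn: float
    iai: float
    classification: str
    per_replicate: list[float] = field(default_factory=list)
    notes: str = "boundary IAI == 4 classified as antagonism"


def classify_interaction(iai: float) -> str:
    """Classify a positive interaction index.

    ≤ 0.5 synergism; strictly between 0.5 and 4 additive; ≥ 4 antagonism.
    """
    if not np.isfinite(iai) or iai <= 0:
        raise DomainError(f"interaction index must be positive, got {iai}")
    if iai <= SYNERGISM_CUTOFF:
        return "synergism"
    if iai >= ANTAGONISM_CUTOFF:
        return "antagonism"
    return "additive"


def interaction_index(e_dza: float, e_arg: float, e_zn: float) -> InteractionResult:
    """Interaction index from the three treatment-group moduli (any common unit)."""
    for name, e in (("E_dza", e_dza), ("E_arg", e_arg), ("E_zn", e_zn)):
        if not np.isfinite(e) or e <= 0:
            raise DomainError(f"{name} must be positive and finite, got {e}")
    iai_arg = e_dza / e_arg
    iai_zn = e_dza / e_zn
    iai = iai_arg + iai_zn
    return InteractionResult(
        iai_arg=iai_arg, iai_zn=iai_zn, iai=iai, classification=classify_interaction(iai)
    )


def _group_moduli(table: ModulusTable, group: str) -> np.ndarray:
    e = table.moduli(group)
    if e.size == 0:
        raise PairingError(f"group {group!r} has no replicates in the modulus table")
    return e


def replicate_interaction_summary(
    table: ModulusTable, pairing: str = "matched"
) -> tuple[float, float, list[float]]:
    """Mean ± SD of the interaction index across replicates.

    ``pairing="matched"`` pairs the i-th replicate (by sorted replicate id)
    of the DZA, arginine, and zinc groups; replicate counts must then be
    equal.  ``pairing="all-combinations"`` evaluates every cross-group
    triple, as a sensitivity analysis.  SD uses ddof=1.
    """
    e_dza = _group_moduli(table, GROUP_DZA)
    e_arg = _group_moduli(table, GROUP_ARG)
    e_zn = _group_moduli(table, GROUP_ZN)
    if pairing == "matched":
        if not (e_dza.size == e_arg.size == e_zn.size):
            raise PairingError(
                f"matched pairing needs equal replicate counts "
                f"(dza={e_dza.size}, arginine={e_arg.size}, zinc={e_zn.size}); "
                f"consider pairing='all-combinations'")
        if e_dza.size < 2:
            raise PairingError("need at least 2 replicates per group")
        values = [interaction_index(d, a, z).iai for d, a, z in zip(e_dza, e_arg, e_zn)]
    elif pairing == "all-combinations":
        if min(e_dza.size, e_arg.size, e_zn.size) < 2:
            raise PairingError("need at least 2 replicates per group")
        values = [
            interaction_index(d, a, z).iai
            for d in e_dza for a in e_arg for z in e_zn
        ]
    else:
        raise DomainError(f"unknown pairing {pairing!r}")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1)), values


def modulus_difference_and_ratio(e_arg: float, e_zn: float) -> tuple[float, float]:
    """Arginine-minus-zinc modulus difference and arginine/zinc ratio."""
    for name, e in (("E_arg", e_arg), ("E_zn", e_zn)):
        if not np.isfinite(e) or e <= 0:
            raise DomainError(f"{name} must be positive and finite, got {e}")
    return e_arg - e_zn, e_arg / e_zn


def replicate_difference_ratio_summary(
    table: ModulusTable, pairing: str = "matched"
) -> dict[str, float]:
    """Mean ± SD of the per-replicate modulus difference and ratio."""
    e_arg = _group_moduli(table, GROUP_ARG)
    e_zn = _group_moduli(table, GROUP_ZN)
    if pairing == "matched":
        if e_arg.size != e_zn.size:
            raise PairingError(
                f"matched pairing needs equal replicate counts "
                f"(arginine={e_arg.size}, zinc={e_zn.size})")
        pairs = list(zip(e_arg, e_zn))
    elif pairing == "all-combinations":
        pairs = [(a, z) for a in e_arg for z in e_zn]
    else:
        raise DomainError(f"unknown pairing {pairing!r}")
    if len(pairs) < 2:
        raise PairingError("need at least 2 replicate pairs")
    diffs = np.array([a - z for a, z in pairs])
    ratios = np.array([a / z for a, z in pairs])
    return {
        "difference_mean": float(diffs.mean()),
        "difference_sd": float(diffs.std(ddof=1)),
        "ratio_mean": float(ratios.mean()),
        "ratio_sd": float(ratios.std(ddof=1)),
    }
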