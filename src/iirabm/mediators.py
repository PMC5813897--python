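"""Cytokine/mediator registry and per-mediator transport constants.

Twelve soluble mediators drive the model's inflammatory dynamics and are
the targets of intervention: platelet-activating factor (PAF), TNF-alpha,
soluble TNF receptor (sTNFr), IL-1, soluble IL-1 receptor (sIL1r), the
IL-1 receptor antagonist (IL1ra), IFN-gamma, IL-4, IL-8, IL-10, IL-12 and
G-CSF.  The canonical ordering below is fixed: intervention multiplier
vectors and chromosomes index mediators in this order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MEDIATORS: tuple[str, ...] = (
    "PAF",
    "TNF",
    "sTNFr",
    "IL1",
    "sIL1r",
    "IL1ra",
    "IFNg",
    "IL4",
    "IL8",
    "IL10",
    "IL12",
    "GCSF",
)

N_MEDIATORS = len(MEDIATORS)

MEDIATOR_INDEX: dict[str, int] = {name: i for i, name in enumerate(MEDIATORS)}

# Short aliases used throughout the dynamics code.
PAF, TNF, STNFR, IL1, SIL1R, IL1RA, IFNG, IL4, IL8, IL10, IL12, GCSF = range(
    N_MEDIATORS
)


@dataclass(frozen=True)
class MediatorSpec:
    """Transport constants for one mediator field.

    Parameters
    ----------
    name
        Mediator name; must be one of :data:`MEDIATORS`.
    diffusion_constant
        Dimensionless per-step diffusion coupling ``D`` to the Moore
        8-neighbourhood mean.  Must lie in ``[0, 1]`` and satisfy
        ``D + lam <= 1`` so a single application can never drive a
        non-negative field negative.
    degradation_constant
        Per-step first-order degradation fraction ``lam`` in ``[0, 1]``.
    """

    name: str
    diffusion_constant: float
    degradation_constant: float

    def __post_init__(self) -> None:
        if self.name not in MEDIATOR_INDEX:
            raise ValueError(f"unknown mediator name {self.name!r}")
        d, lam = self.diffusion_constant, self.degradation_constant
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"{self.name}: diffusion constant {d} outside [0, 1]")
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"{self.name}: degradation constant {lam} outside [0, 1]")
        if d + lam > 1.0:
            raise ValueError(
                f"{self.name}: D + lambda = {d + lam} > 1 would allow negative "
                "concentrations in a single update"
            )


# Default transport table.  Small, fast-acting lipid/chemokine signals (PAF,
# IL-8) diffuse and degrade quickly; soluble receptors and growth factors
# persist longer.  Values are per 7.2-minute step.
DEFAULT_MEDIATOR_SPECS: tuple[MediatorSpec, ...] = (
    MediatorSpec("PAF", 0.6, 0.3),
    MediatorSpec("TNF", 0.5, 0.15),
    MediatorSpec("sTNFr", 0.4, 0.05),
    MediatorSpec("IL1", 0.5, 0.15),
    MediatorSpec("sIL1r", 0.4, 0.05),
    MediatorSpec("IL1ra", 0.4, 0.05),
    MediatorSpec("IFNg", 0.4, 0.10),
    MediatorSpec("IL4", 0.4, 0.10),
    MediatorSpec("IL8", 0.6, 0.20),
    MediatorSpec("IL10", 0.4, 0.10),
    MediatorSpec("IL12", 0.4, 0.10),
    MediatorSpec("GCSF", 0.4, 0.05),
)


def spec_arrays(specs: list[MediatorSpec] | tuple[MediatorSpec, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(D, lam)`` arrays in canonical mediator order."""
    if len(specs) != N_MEDIATORS:
        raise ValueError(f"expected {N_MEDIATORS} mediator specs, got {len(specs)}")
    by_name = {s.name: s for s in specs}
    missing = set(MEDIATORS) - set(by_name)
    if missing:
        raise ValueError(f"missing mediator specs: {sorted(missing)}")
    d = np.array([by_name[m].diffusion_constant for m in MEDIATORS])
    lam = np.array([by_name[m].degradation_constant for m in MEDIATORS])
    return d, lam
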