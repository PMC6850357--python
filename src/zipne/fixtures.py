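"""Micro encounter datasets (M <= 3, T <= 3) for exact cross-checks.

These instances are small enough that the composite likelihood can be
recomputed by brute force — exhaustive enumeration of all three-state paths
combined with fine-grid numerical integration over the individual effects —
so they anchor the quadrature/HMM implementation against an independent
oracle.
"""

from __future__ import annotations

import numpy as np

from zipne.data_model import EncounterData

__all__ = ["micro_datasets", "micro_params"]


def micro_datasets() -> dict[str, EncounterData]:
    """Named micro instances used by the oracle cross-checks."""
    out: dict[str, EncounterData] = {}
    # one individual, one occasion, never sighted
    out["m1_t1_zero"] = EncounterData(
        T=1, y=[[0]], b=[1], e=[0], u=[3], R=[1],
        n_known=[True], n=[1],
    )
    # two individuals, two occasions, second released at occasion 2
    out["m2_t2"] = EncounterData(
        T=2, y=[[0, 3], [0, 1]], b=[1, 2], e=[1, 2], u=[8, 5], R=[1, 1],
        n_known=[True, False], n=[1, 0],
    )
    # three individuals, three occasions, mixed histories incl. an all-zero row
    out["m3_t3"] = EncounterData(
        T=3, y=[[2, 0, 1], [0, 0, 0], [0, 4, 0]], b=[1, 1, 2],
        e=[1, 0, 2], u=[12, 9, 7], R=[2, 1, 0],
        n_known=[True, False, False], n=[2, 0, 0],
    )
    return out


def micro_params(T: int) -> dict[str, np.ndarray]:
    """Interior (non-boundary) parameter values for a micro instance.

    Mildly time-varying so that no accidental symmetry hides an indexing
    mistake; returned as keyword arguments for :class:`ParameterSet`.
    """
    base = dict(
        alpha=np.linspace(0.3, 0.7, T),
        sigma=np.linspace(0.4, 0.6, T),
        r=np.linspace(0.85, 0.75, T),
        w=np.linspace(0.9, 0.8, T),
        g=np.linspace(0.85, 0.9, T),
        U=np.linspace(20.0, 15.0, T),
    )
    if T > 1:
        base.update(
            phi=np.linspace(0.9, 0.85, T - 1),
            gammaPP=np.linspace(0.15, 0.2, T - 1),
            gammaP=np.linspace(0.25, 0.2, T - 1),
        )
    else:
        base.update(phi=np.zeros(0), gammaPP=np.zeros(0), gammaP=np.zeros(0))
    return base
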