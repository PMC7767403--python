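"""Linear Interaction Energy (LIE) binding free energies and the
four-system relative binding free energy.

For one variant the LIE estimate of the binding free energy is

    dG_bind = alpha * (<E_vdw>_bound - <E_vdw>_unbound)
            + beta  * (<E_el>_bound  - <E_el>_unbound)

with the averages taken over the ligand--surrounding interaction-energy
samples of the bound (protein-DNA complex) and unbound (free DNA)
simulations, and empirical parameters alpha = 0.18, beta = 0.43.
Entropic contributions are implicit in the parametrisation of alpha and
beta; no explicit entropy term is computed.

The wild-type vs mutant comparison closes a four-system thermodynamic
cycle {AT, GC} x {Complex, DNA}:

    ddG_bind = dG_bind(GC) - dG_bind(AT)

which decomposes exactly into an electrostatic (beta) and a van der
Waals (alpha) component. A negative ddG_bind means the mutant base pair
binds the transcription factor more strongly.

Uncertainties: sample means get block-averaging standard errors (MD
energy series are autocorrelated, so naive SEs would be optimistic);
single-cycle SEs propagate as the root sum of squares of the four
scaled cell SEs; replicate runs are pooled as an unweighted mean with
the SE of the per-run values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import ENVIRONMENTS, VARIANTS, EnergySeries

__all__ = [
    "LIEParams",
    "MeanEnergies",
    "DeltaG",
    "LIEResult",
    "mean_interaction_energies",
    "lie_delta_g",
    "ddg_bind",
    "pool_runs",
]


@dataclass(frozen=True)
class LIEParams:
    """Empirical LIE coefficients (dimensionless)."""

    alpha: float = 0.18  # scales the van der Waals difference
    beta: float = 0.43  # scales the electrostatic difference

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")


@dataclass(frozen=True)
class MeanEnergies:
    """Average interaction energies of one (variant, environment) system."""

    variant: str
    environment: str
    mean_vdw: float
    mean_el: float
    se_vdw: float = 0.0
    se_el: float = 0.0
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"environment must be one of {ENVIRONMENTS}")
        if self.se_vdw < 0 or self.se_el < 0:
            raise ValueError("standard errors must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class DeltaG:
    """A single-variant LIE binding free energy with its components."""

    variant: str
    total: float
    el_component: float
    vdw_component: float
    se: float = 0.0


@dataclass
class LIEResult:
    """The four-system cycle result (single run or pooled over runs)."""

    dg_bind_at: float
    dg_bind_gc: float
    ddg: float
    ddg_el_component: float
    ddg_vdw_component: float
    se_ddg: float
    per_run: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["run", "ddg", "el_component", "vdw_component", "se_ddg"]
        )
    )

    def __post_init__(self) -> None:
        if abs(self.ddg - (self.ddg_el_component + self.ddg_vdw_component)) > 1e-10:
            raise ValueError("component decomposition does not sum to ddg")
        if abs(self.ddg - (self.dg_bind_gc - self.dg_bind_at)) > 1e-10:
            raise ValueError("ddg must equal dg_bind_gc - dg_bind_at")


def mean_interaction_energies(series: EnergySeries, block_count: int = 10) -> MeanEnergies:
    """Sample means with block-averaging standard errors.

    The series is cut into ``block_count`` contiguous equal-size blocks
    (trailing remainder samples are dropped from the SE estimate only);
    the SE is the standard deviation of the block means over
    sqrt(block_count). Means are over all samples.
    """
    if block_count < 2:
        raise ValueError("block_count must be >= 2")
    n = len(series)
    if n < block_count:
        raise ValueError(f"series of {n} samples cannot form {block_count} blocks")

    def _se(x: np.ndarray) -> float:
        block = n // block_count
        trimmed = x[: block * block_count].reshape(block_count, block)
        means = trimmed.mean(axis=1)
        return float(means.std(ddof=1) / np.sqrt(block_count))

    return MeanEnergies(
        variant=series.variant,
        environment=series.environment,
        mean_vdw=float(series.e_vdw.mean()),
        mean_el=float(series.e_el.mean()),
        se_vdw=_se(series.e_vdw),
        se_el=_se(series.e_el),
        n_samples=n,
    )


def lie_delta_g(
    bound: MeanEnergies,
    unbound: MeanEnergies,
    params: LIEParams = LIEParams(),
) -> DeltaG:
    """LIE binding free energy for one variant (kcal/mol)."""
    if bound.variant != unbound.variant:
        raise ValueError(
            f"variant mismatch: bound is {bound.variant}, unbound {unbound.variant}"
        )
    if bound.environment != "Complex" or unbound.environment != "DNA":
        raise ValueError(
            "expected bound.environment='Complex' and unbound.environment='DNA'"
        )
    vdw = params.alpha * (bound.mean_vdw - unbound.mean_vdw)
    el = params.beta * (bound.mean_el - unbound.mean_el)
    se = float(
        np.sqrt(
            (params.alpha * bound.se_vdw) ** 2
            + (params.alpha * unbound.se_vdw) ** 2
            + (params.beta * bound.se_el) ** 2
            + (params.beta * unbound.se_el) ** 2
        )
    )
    return DeltaG(
        variant=bound.variant,
        total=vdw + el,
        el_component=el,
        vdw_component=vdw,
        se=se,
    )


def _cells(four: list[MeanEnergies] | tuple[MeanEnergies, ...] | dict) -> dict:
    if isinstance(four, dict):
        cells = dict(four)
    else:
        cells = {}
        for m in four:
            key = (m.variant, m.environment)
            if key in cells:
                raise ValueError(f"duplicate cell {key}")
            cells[key] = m
    missing = [
        (v, e) for v in VARIANTS for e in ENVIRONMENTS if (v, e) not in cells
    ]
    if missing:
        raise ValueError(f"incomplete thermodynamic cycle; missing cells: {missing}")
    return cells


def ddg_bind(
    four: list[MeanEnergies] | tuple[MeanEnergies, ...] | dict,
    params: LIEParams = LIEParams(),
    run_label: str | int = 0,
) -> LIEResult:
    """Relative binding free energy from one complete four-system cycle.

    ``four`` holds exactly one :class:`MeanEnergies` per (variant,
    environment) cell; a missing cell raises an incomplete-cycle error.
    The SE is propagated as the root sum of squares of the eight scaled
    cell SEs (alpha on vdW, beta on electrostatics).
    """
    cells = _cells(four)
    dg_at = lie_delta_g(cells[("AT", "Complex")], cells[("AT", "DNA")], params)
    dg_gc = lie_delta_g(cells[("GC", "Complex")], cells[("GC", "DNA")], params)
    ddg_el = dg_gc.el_component - dg_at.el_component
    ddg_vdw = dg_gc.vdw_component - dg_at.vdw_component
    se = float(np.sqrt(dg_at.se**2 + dg_gc.se**2))
    ddg = ddg_el + ddg_vdw
    per_run = pd.DataFrame(
        [
            {
                "run": run_label,
                "ddg": ddg,
                "el_component": ddg_el,
                "vdw_component": ddg_vdw,
                "se_ddg": se,
            }
        ]
    )
    return LIEResult(
        dg_bind_at=dg_at.total,
        dg_bind_gc=dg_gc.total,
        ddg=ddg,
        ddg_el_component=ddg_el,
        ddg_vdw_component=ddg_vdw,
        se_ddg=se,
        per_run=per_run,
    )


def pool_runs(per_run: list[LIEResult] | tuple[LIEResult, ...]) -> LIEResult:
    """Pool replicate single-run cycles as an unweighted mean.

    The pooled SE is the (population) standard deviation of the per-run
    ddG values over sqrt(n_runs), i.e. the replicates themselves supply
    the uncertainty; block SEs within runs stay in the per-run table.
    """
    if len(per_run) < 2:
        raise ValueError(
            "pooling needs >= 2 runs; report the single run's result directly"
        )
    table = pd.concat([r.per_run for r in per_run], ignore_index=True)
    n = len(per_run)
    ddg = float(np.mean([r.ddg for r in per_run]))
    ddg_el = float(np.mean([r.ddg_el_component for r in per_run]))
    ddg_vdw = float(np.mean([r.ddg_vdw_component for r in per_run]))
    dg_at = float(np.mean([r.dg_bind_at for r in per_run]))
    dg_gc = float(np.mean([r.dg_bind_gc for r in per_run]))
    se = float(np.std([r.ddg for r in per_run], ddof=0) / np.sqrt(n))
    # recentre so the invariant identities hold exactly despite float summation
    return LIEResult(
        dg_bind_at=dg_at,
        dg_bind_gc=dg_at + (ddg_el + ddg_vdw),
        ddg=ddg_el + ddg_vdw,
        ddg_el_component=ddg_el,
        ddg_vdw_component=ddg_vdw,
        se_ddg=se,
        per_run=table,
    )
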