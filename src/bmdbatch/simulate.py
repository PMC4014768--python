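"""Synthetic dose-response data with known truth.

Generates datasets from a declared true model: binomial counts for
dichotomous designs and normal individual responses (summarized to group
mean/SD, the way study tables report them) for continuous designs.  Used for
parameter-recovery checks, BMDL coverage studies, and simulation sweeps over
study-design factors (number of dose groups, animals per group, dose spacing).

Default designs mimic common toxicology bioassays: a control plus nonzero
doses in geometric progression with ratio sqrt(10), with the top dose placed
about 10x above the dose region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import RunConfig
from .datasets import CONTINUOUS, DoseResponseDataset
from .models import ContinuousSpec, ModelSpec
from .rules import run_dataset

#: default geometric spacing between adjacent nonzero doses
DEFAULT_DOSE_RATIO = float(np.sqrt(10.0))


@dataclass
class SimDesign:
    """A simulated study design with a known true dose-response model.

    Parameters
    ----------
    true_spec : ModelSpec
        The generating model (its ``dtype`` sets the dataset type).
    true_params : sequence of float
        True parameter vector.  For continuous designs this is the mean
        function only; noise comes from ``sigma`` or ``(alpha, rho)``.
    n_groups : int
        Number of dose groups including the control at dose 0.
    n_per_group : int or sequence of int
    dose_pattern : str
        ``geometric`` (ratio sqrt(10) down from the top dose), ``arithmetic``
        (evenly spaced), or ``custom`` (``doses`` given explicitly).
    top_dose : float
        Highest dose (ignored for custom patterns).
    doses : sequence, optional
        Explicit doses for the custom pattern (must start at 0).
    sigma : float, optional
        Constant true SD of individual responses (continuous).
    alpha, rho : float, optional
        Power-variance truth Var(d) = alpha * |mu(d)|^rho (continuous).
    seed : int
        Reproducibility: the same design always yields the same dataset.
    """

    true_spec: ModelSpec
    true_params: Sequence[float]
    n_groups: int = 4
    n_per_group: Union[int, Sequence[int]] = 10
    dose_pattern: str = "geometric"
    top_dose: float = 100.0
    doses: Optional[Sequence[float]] = None
    sigma: Optional[float] = None
    alpha: Optional[float] = None
    rho: Optional[float] = None
    seed: int = 0
    dataset_id: str = "sim"
    chemical_id: Optional[str] = None

    def dose_vector(self) -> np.ndarray:
        if self.dose_pattern == "custom":
            d = np.asarray(self.doses, dtype=float)
            if d[0] != 0:
                raise ValueError("custom dose vectors must include a control at 0")
            return d
        k = self.n_groups - 1  # nonzero doses
        if k < 1:
            raise ValueError("need at least one nonzero dose group")
        if self.dose_pattern == "geometric":
            nz = self.top_dose / DEFAULT_DOSE_RATIO ** np.arange(k - 1, -1, -1)
        elif self.dose_pattern == "arithmetic":
            nz = np.linspace(self.top_dose / k, self.top_dose, k)
        else:
            raise ValueError(f"unknown dose pattern {self.dose_pattern!r}")
        return np.concatenate([[0.0], nz])

    def group_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_group):
            return np.full(self.n_groups, int(self.n_per_group))
        n = np.asarray(self.n_per_group, dtype=int)
        if len(n) != self.n_groups:
            raise ValueError("n_per_group list must match n_groups")
        return n


def simulate_dataset(design: SimDesign,
                     rng: Optional[np.random.Generator] = None) -> DoseResponseDataset:
    """Draw one dataset from the design's true model."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    doses = design.dose_vector()
    n = design.group_sizes()
    spec = design.true_spec
    params = np.asarray(design.true_params, dtype=float)

    if spec.dtype == CONTINUOUS or isinstance(spec, ContinuousSpec):
        mu = spec.predict(params, doses)
        if design.sigma is not None:
            sd_true = np.full_like(mu, float(design.sigma))
        elif design.alpha is not None:
            rho = 0.0 if design.rho is None else float(design.rho)
            sd_true = np.sqrt(design.alpha * np.maximum(np.abs(mu), 1e-8) ** rho)
        else:
            raise ValueError("continuous designs need sigma or (alpha, rho)")
        means, sds = [], []
        for mu_i, sd_i, n_i in zip(mu, sd_true, n):
            # draw individuals, then summarize as a study table would
            x = rng.normal(mu_i, sd_i, size=int(n_i))
            means.append(float(np.mean(x)))
            sds.append(float(np.std(x, ddof=1)) if n_i > 1 else 0.0)
        return DoseResponseDataset(
            dataset_id=design.dataset_id, dtype=CONTINUOUS, doses=doses, n=n,
            mean=np.array(means), sd=np.array(sds),
            chemical_id=design.chemical_id,
        )

    p = spec.predict(params, doses)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("true parameters give probabilities outside [0, 1]")
    y = rng.binomial(n, p)
    return DoseResponseDataset(
        dataset_id=design.dataset_id, dtype=spec.dtype, doses=doses, n=n,
        incidence=y, chemical_id=design.chemical_id,
    )


def simulate_many(design: SimDesign, reps: int, seed: Optional[int] = None) -> list:
    """Independent replicate datasets from one design (seeded stream)."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    out = []
    for i in range(reps):
        ds = simulate_dataset(design, rng=rng)
        ds.dataset_id = f"{design.dataset_id}-{i}"
        out.append(ds)
    return out


def design_sweep(designs: Sequence[SimDesign], config: Optional[RunConfig] = None,
                 reps: int = 100, seed: int = 0) -> pd.DataFrame:
    """Run a factorial grid of designs through the full batch workflow.

    For each design cell, ``reps`` replicate datasets are generated and run
    through :func:`bmdbatch.rules.run_dataset`; the returned table reports the
    fraction of replicates that were successfully modeled (at least one
    Viable fit) plus the mean selected BMD and BMDL among modeled replicates.
    """
    config = config or RunConfig()
    rows = []
    for cell_index, design in enumerate(designs):
        rng = np.random.default_rng((seed, design.seed, cell_index))
        modeled = 0
        bmds, bmdls = [], []
        for _ in range(reps):
            ds = simulate_dataset(design, rng=rng)
            rec = run_dataset(ds, config)
            if rec.outcome == "modeled":
                modeled += 1
                bmds.append(rec.selected.bmd)
                bmdls.append(rec.selected.bmdl)
        rows.append(
            {
                "n_groups": design.n_groups,
                "n_per_group": int(np.mean(design.group_sizes())),
                "dose_pattern": design.dose_pattern,
                "top_dose": design.top_dose,
                "reps": reps,
                "n_modeled": modeled,
                "viability_fraction": modeled / reps,
                "mean_bmd": float(np.mean(bmds)) if bmds else np.nan,
                "mean_bmdl": float(np.mean(bmdls)) if bmdls else np.nan,
            }
        )
    return pd.DataFrame(rows)
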