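"""Synthetic cohort-style risk summaries with known ground truth.

Real parameterizations of the model come from published cohort
summaries: ERR-vs-dose points for radiotherapy and RR-vs-cycle-group
tables for chemotherapy and concurrent therapy.  This module generates
datasets of the same shape from a chosen "truth" parameter set, with an
optional multiplicative lognormal noise model applied to the *excess*
risk (so a noisy RR can fall below 1, as published point estimates do,
but the RR = 1 floor of a null effect is respected).  Every dataset is
reproducible from its seed, and the generating truth is returned
alongside so that recovery tests never re-derive it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .fitting import ErrDataPoint, RrDataPoint
from .model_core import ChemoCourse, OrganParams, dose_response_curve, relative_risk

__all__ = ["SyntheticSpec", "generate_err_dataset", "generate_rr_dataset", "write_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``design`` holds the design points: doses (Gy) for ERR datasets or
    cycle counts for RR datasets.  ``cv`` is the coefficient of
    variation of the multiplicative lognormal noise; the lognormal
    sigma is ``sqrt(log(1 + cv^2))``.
    """

    params: OrganParams
    design: tuple = ()
    noise: str = "none"
    cv: float = 0.3
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise not in ("none", "lognormal_cv"):
            raise ValueError("noise must be 'none' or 'lognormal_cv'")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise != "none" and self.seed is None:
            raise ValueError("a seed is mandatory when noise is not 'none'")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log(1.0 + self.cv**2))

    def truth_record(self) -> dict:
        d = {f: getattr(self.params, f) for f in OrganParams.__dataclass_fields__}
        d.update(
            design=list(self.design),
            noise=self.noise,
            cv=self.cv,
            n_replicates=self.n_replicates,
            seed=self.seed,
        )
        return d


def _noise_factors(spec: SyntheticSpec, size: int) -> np.ndarray:
    if spec.noise == "none":
        return np.ones(size)
    rng = np.random.default_rng(spec.seed)
    return np.exp(rng.normal(0.0, spec.sigma, size=size))


def generate_err_dataset(
    spec: SyntheticSpec,
    fractionation: str = "fixed_count",
) -> tuple[list[ErrDataPoint], dict]:
    """ERR-vs-dose points: ``ERR_obs = ERR_model(D; truth) * LogNormal``."""
    doses = list(spec.design)
    if not doses:
        return [], spec.truth_record()
    curve = dose_response_curve(spec.params, doses, fractionation=fractionation)
    truth_err = np.repeat(curve["ERR"].to_numpy(), spec.n_replicates)
    all_doses = np.repeat(np.asarray(doses, dtype=float), spec.n_replicates)
    obs = truth_err * _noise_factors(spec, truth_err.size)
    points = [ErrDataPoint(dose=float(d), err=float(e)) for d, e in zip(all_doses, obs)]
    return points, spec.truth_record()


def generate_rr_dataset(
    spec: SyntheticSpec,
    course_template: Callable[[int], object] | None = None,
) -> tuple[list[RrDataPoint], dict]:
    """RR-vs-cycles points with lognormal noise on the excess risk.

    ``course_template`` maps a cycle count to a ``ChemoCourse`` or
    ``ConcurrentCourse``; by default plain chemotherapy cycles.
    """
    template = course_template or (lambda cycles: ChemoCourse(K_C=int(cycles)))
    cycles = list(spec.design)
    if not cycles:
        return [], spec.truth_record()
    truth_excess = np.array(
        [relative_risk(spec.params, template(int(k))).ERR for k in cycles]
    )
    excess = np.repeat(truth_excess, spec.n_replicates)
    all_cycles = np.repeat(np.asarray(cycles, dtype=int), spec.n_replicates)
    obs = 1.0 + excess * _noise_factors(spec, excess.size)
    points = [
        RrDataPoint(cycles=int(k), rr=float(v)) for k, v in zip(all_cycles, obs)
    ]
    return points, spec.truth_record()


def write_dataset(points: Sequence, truth: dict, csv_path: str | Path) -> Path:
    """Write a dataset CSV plus its ``*.truth.json`` sidecar."""
    import pandas as pd

    csv_path = Path(csv_path)
    if points and isinstance(points[0], ErrDataPoint):
        df = pd.DataFrame([(p.dose, p.err) for p in points], columns=["dose", "value"])
    else:
        df = pd.DataFrame([(p.cycles, p.rr) for p in points], columns=["cycles", "value"])
    df["ci_low"] = np.nan
    df["ci_high"] = np.nan
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2))
    return sidecar
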