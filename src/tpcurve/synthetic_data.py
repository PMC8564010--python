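"""Synthetic survival data with the statistical structure the analysis assumes.

Generates individual-level binary outcomes from logit-scale cubic performance
curves with block and vial random intercepts, on a split-cohort factorial
layout: 2 fertilization x 3 embryogenesis treatment temperatures crossed with
a grid of assay temperatures, replicate vials allocated to blocks either in
an incomplete block design (each block receives a subset of assay
temperatures) or round-robin ("balanced" spread).

Curves can be specified either as raw cubic coefficients of the logit-scale
polynomial eta(T) = b0 + b1*T + b2*T^2 + b3*T^3, or by descriptors
(peak logit height, true optimum, quadratic width, optional cubic skew):

    eta(T) = peak_logit + quad * (T - topt)^2 + cubic * (T - topt)^3

The quadratic-in-logit default (cubic = 0) gives closed-form true
descriptors for testing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

from .data_model import ExperimentDesign, SurvivalRecord, SurvivalTable, default_design

__all__ = ["CurveParams", "GeneratorConfig", "simulate_dataset", "paper_like_config"]

logger = logging.getLogger(__name__)

#: logit values beyond this are clamped before the Bernoulli draw
ETA_CLAMP = 36.0


@dataclass(frozen=True)
class CurveParams:
    """Logit-scale cubic curve for one (fert_temp, embryo_temp) group."""

    b0: float
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0

    @classmethod
    def from_descriptors(
        cls, peak_logit: float, topt: float, quad: float, cubic: float = 0.0
    ) -> "CurveParams":
        """Build from a peak-centered parameterization.

        ``quad`` must be negative for a genuine peak.  The returned raw
        coefficients expand peak_logit + quad*(T-topt)^2 + cubic*(T-topt)^3.
        """
        if quad >= 0:
            raise ValueError("quad must be < 0 so the curve has a peak")
        c = topt
        b0 = peak_logit + quad * c * c - cubic * c**3
        b1 = -2.0 * quad * c + 3.0 * cubic * c * c
        b2 = quad - 3.0 * cubic * c
        b3 = cubic
        return cls(b0=b0, b1=b1, b2=b2, b3=b3)

    def eta(self, temps) -> np.ndarray:
        t = np.asarray(temps, dtype=float)
        return self.b0 + self.b1 * t + self.b2 * t * t + self.b3 * t**3

    def coeffs(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3])


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generative specification: design, group curves, random-effect SDs."""

    design: ExperimentDesign
    curve_params: Mapping[tuple[float, float], CurveParams]
    sigma_block: float = 0.0
    sigma_vial: float = 0.0
    seed: int = 0
    allocation: str = "incomplete"  # "incomplete" or "balanced"

    def validate(self) -> None:
        self.design.validate()
        if self.sigma_block < 0 or self.sigma_vial < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.allocation not in ("incomplete", "balanced"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        for f in self.design.fert_temps:
            for e in self.design.embryo_temps:
                if (f, e) not in self.curve_params:
                    raise ValueError(f"no curve parameters for group (fert={f}, embryo={e})")


def _stable_hash(*parts) -> int:
    h = hashlib.blake2b("|".join(str(p) for p in parts).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big")


def _allocate_vials(design: ExperimentDesign, rng: np.random.Generator, allocation: str):
    """Assign replicate vials of each assay temperature to blocks.

    Returns a list of (block_index, assay_temp, replicate_index) triples.
    Incomplete allocation fills each temperature's replicate quota greedily
    onto the least-loaded blocks (seeded tie-breaking), respecting the
    design's per-block temperature-count cap where feasible; balanced
    allocation spreads replicates round-robin over blocks deterministically.
    """
    temps = list(design.assay_temps)
    nb = design.n_blocks
    slots: list[tuple[int, float, int]] = []
    if allocation == "balanced":
        counter = 0
        for t in temps:
            for r in range(design.replicates_per_combo[t]):
                slots.append((counter % nb, t, r))
                counter += 1
        return slots

    cap = design.temps_per_block[1]
    load = np.zeros(nb, dtype=int)
    block_temps: list[set[float]] = [set() for _ in range(nb)]
    order = list(temps)
    rng.shuffle(order)
    for t in order:
        quota = design.replicates_per_combo[t]
        # candidate blocks not yet holding t, least-loaded first
        for r in range(quota):
            cands = [b for b in range(nb) if t not in block_temps[b]]
            if not cands:
                raise ValueError(
                    f"replicate quota for {t} exceeds the number of blocks"
                )
            under_cap = [b for b in cands if load[b] < cap]
            pool = under_cap or cands
            min_load = min(load[b] for b in pool)
            pool = [b for b in pool if load[b] == min_load]
            b = int(pool[rng.integers(len(pool))])
            block_temps[b].add(t)
            load[b] += 1
            slots.append((b, t, r))
    return sorted(slots, key=lambda s: (s[0], s[1], s[2]))


def simulate_dataset(config: GeneratorConfig) -> SurvivalTable:
    """Draw a survival table from the generative model. Deterministic per seed.

    For each block a random intercept u_b ~ N(0, sigma_block^2) is drawn;
    each vial adds v ~ N(0, sigma_vial^2); each individual's outcome is
    Bernoulli(expit(eta_group(T) + u_b + v)).  Sub-streams are derived by
    stable hashing of block/vial identity so adding blocks does not perturb
    earlier ones.
    """
    config.validate()
    design = config.design
    seed = config.seed

    alloc_rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    slots = _allocate_vials(design, alloc_rng, config.allocation)

    records: list[SurvivalRecord] = []
    n_clamped = 0
    block_u: dict[int, float] = {}
    for b in sorted({s[0] for s in slots}):
        rng_b = np.random.default_rng(np.random.SeedSequence((seed, 1, _stable_hash("block", b))))
        block_u[b] = float(rng_b.normal(0.0, config.sigma_block))

    for b, t, r in slots:
        for f in design.fert_temps:
            for e in design.embryo_temps:
                vial_id = f"B{b + 1:02d}_F{f:g}_E{e:g}_T{t:g}_r{r + 1}"
                rng_v = np.random.default_rng(
                    np.random.SeedSequence((seed, 2, _stable_hash("vial", b, f, e, t, r)))
                )
                v = float(rng_v.normal(0.0, config.sigma_vial))
                eta = float(config.curve_params[(f, e)].eta(t)) + block_u[b] + v
                if abs(eta) > ETA_CLAMP:
                    eta = float(np.clip(eta, -ETA_CLAMP, ETA_CLAMP))
                    n_clamped += 1
                p = float(expit(eta))
                outcomes = rng_v.random(design.n_per_vial) < p
                block_id = f"B{b + 1:02d}"
                for y in outcomes:
                    records.append(
                        SurvivalRecord(
                            block_id=block_id,
                            vial_id=vial_id,
                            fert_temp=f,
                            embryo_temp=e,
                            assay_temp=t,
                            outcome=int(y),
                        )
                    )
    if n_clamped:
        logger.warning("clamped |eta| > %.0f in %d vials", ETA_CLAMP, n_clamped)
    table = SurvivalTable(records=records, design=design)
    table.validate()
    return table


def paper_like_config(
    topt_by_embryo: Mapping[float, float],
    seed: int = 0,
    design: ExperimentDesign | None = None,
    peak_logit: float = 2.0,
    quad: float = -0.05,
    cubic: float = 0.0,
    sigma_block: float = 0.3,
    sigma_vial: float = 0.3,
    allocation: str = "incomplete",
) -> GeneratorConfig:
    """Config with shared peak height/curvature, group optima as given, and no
    fertilization effect.  The analytic argmax of each group's logit curve
    equals the supplied optimum exactly (when ``cubic`` is 0)."""
    design = design or default_design()
    if set(topt_by_embryo) != set(design.embryo_temps):
        raise ValueError("topt_by_embryo must supply every embryogenesis level")
    params = {}
    for f in design.fert_temps:
        for e in design.embryo_temps:
            params[(f, e)] = CurveParams.from_descriptors(
                peak_logit=peak_logit, topt=topt_by_embryo[e], quad=quad, cubic=cubic
            )
    return GeneratorConfig(
        design=design,
        curve_params=params,
        sigma_block=sigma_block,
        sigma_vial=sigma_vial,
        seed=seed,
        allocation=allocation,
    )
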