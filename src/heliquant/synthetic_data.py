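"""Synthetic breeding-design, field-survey and host-plant data.

The generator mirrors a two-generation full-sib/half-sib common-garden
design: about 20 dams each produce one brood, a subset of sires is
identified (one pair of broods sharing a sire yields paternal half-sibs),
and a subset of broods is split evenly across four host-plant feeding
treatments.  Phenotypes (cyanogen concentration, percent of dry mass)
follow

    y = mu + sex + treatment + a + maternal + e

with breeding values ``a`` drawn multivariate normal with covariance
V_A * A from the pedigree, and a maternal term that is either a dam-level
normal deviate (variance V_mat) or, in Falconer transmission mode,
m * (dam phenotype - mu).  Ground-truth parameters default to the scale
of the empirical study (mu = 0.772, V_A = 0.0093, V_P ~ 0.080), so the
downstream estimators can be checked for parameter recovery.

Field populations are drawn from right-skewed nonnegative laws (gamma or
log-normal) with an optional point mass at zero for below-detection
samples; host-plant cyanogen tables are gamma-distributed per site or
per origin x watering-treatment cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import validate_pedigree, additive_relationship_matrix

__all__ = [
    "SimulationConfig",
    "FieldDistribution",
    "make_pedigree",
    "simulate_breeding_phenotypes",
    "simulate_field_population",
    "simulate_hostplants",
]


def _study_brood_sizes():
    # six large treatment broods and fourteen smaller ones, as in the
    # empirical design (averages 29 and 8 full-sibs per brood)
    return (29,) * 6 + (8,) * 14


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated breeding experiment.

    ``offspring_per_brood`` may be a single count, a ``(low, high)``
    range sampled per brood, or an explicit per-brood sequence.
    ``m_transmission`` (Falconer mode) and ``V_mat`` (dam-level variance
    mode) are two distinct maternal-effect mechanisms and may not both be
    nonzero in one run.
    """

    n_broods: int = 20
    offspring_per_brood: object = field(default_factory=_study_brood_sizes)
    n_shared_sire_pairs: int = 1
    n_unknown_sire_broods: int = 6
    n_treatment_broods: int = 6
    mu: float = 0.772
    V_A: float = 0.0093
    V_mat: float = 0.0
    m_transmission: float = 0.0
    sex_effect: float = 0.059
    treatment_effects: tuple = (0.0, 0.04, -0.04, 0.06)
    V_R: float = 0.0703
    linamarin_share: float = 0.747
    share_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_broods < 1:
            raise ValueError("n_broods must be >= 1")
        for name in ("V_A", "V_mat", "V_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.m_transmission != 0.0 and self.V_mat != 0.0:
            raise ValueError(
                "m_transmission and V_mat are alternative maternal-effect "
                "modes and may not both be nonzero"
            )
        if not 0 < self.linamarin_share < 1:
            raise ValueError("linamarin_share must be in (0, 1)")
        if self.n_unknown_sire_broods < 0 or self.n_unknown_sire_broods > self.n_broods:
            raise ValueError("n_unknown_sire_broods must be in [0, n_broods]")
        if self.n_shared_sire_pairs < 0 or self.n_shared_sire_pairs > self.n_broods // 2:
            raise ValueError("n_shared_sire_pairs exceeds floor(n_broods / 2)")
        if 2 * self.n_shared_sire_pairs > self.n_broods - self.n_unknown_sire_broods:
            raise ValueError("not enough known-sire broods for the shared-sire pairs")
        if self.n_treatment_broods < 0 or self.n_treatment_broods > self.n_broods:
            raise ValueError("n_treatment_broods must be in [0, n_broods]")
        sizes = self._brood_sizes_static()
        if sizes is not None and any(s < 1 for s in sizes):
            raise ValueError("offspring_per_brood must be >= 1")

    def _brood_sizes_static(self):
        o = self.offspring_per_brood
        if isinstance(o, (int, np.integer)):
            return [int(o)] * self.n_broods
        if isinstance(o, tuple) and len(o) == 2 and all(
            isinstance(v, (int, np.integer)) for v in o
        ):
            return None  # a range: resolved with the RNG at generation time
        sizes = [int(v) for v in o]
        if len(sizes) != self.n_broods:
            raise ValueError("per-brood offspring sequence length must equal n_broods")
        return sizes

    def brood_sizes(self, rng: np.random.Generator):
        sizes = self._brood_sizes_static()
        if sizes is None:
            lo, hi = self.offspring_per_brood
            if lo < 1 or hi < lo:
                raise ValueError("offspring range must satisfy 1 <= low <= high")
            sizes = rng.integers(lo, hi + 1, size=self.n_broods).tolist()
        return sizes


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def make_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Build a two-generation pedigree per the configuration.

    Each brood has its own dam; the first ``n_shared_sire_pairs`` pairs
    of known-sire broods share a sire (paternal half-sibs); the last
    ``n_unknown_sire_broods`` broods get a distinct phantom founder sire
    (single-mating assumption), flagged in the ``phantom`` column so they
    can be excluded from phenotyping.
    """
    rng = _rng(config, 0)
    nb = config.n_broods
    sizes = config.brood_sizes(rng)
    known = nb - config.n_unknown_sire_broods

    rows = []
    dams = [f"D{b + 1:02d}" for b in range(nb)]
    for d in dams:
        rows.append(dict(id=d, dam=None, sire=None, sex="F", generation="P",
                         brood=None, phantom=False))
    # sires: shared pairs first, then singles, then phantoms
    sires = []
    s_idx = 0
    b = 0
    for _ in range(config.n_shared_sire_pairs):
        s_idx += 1
        sid = f"S{s_idx:02d}"
        rows.append(dict(id=sid, dam=None, sire=None, sex="M", generation="P",
                         brood=None, phantom=False))
        sires.extend([sid, sid])
        b += 2
    while b < known:
        s_idx += 1
        sid = f"S{s_idx:02d}"
        rows.append(dict(id=sid, dam=None, sire=None, sex="M", generation="P",
                         brood=None, phantom=False))
        sires.append(sid)
        b += 1
    for k in range(config.n_unknown_sire_broods):
        sid = f"PS{k + 1:02d}"
        rows.append(dict(id=sid, dam=None, sire=None, sex="M", generation="P",
                         brood=None, phantom=True))
        sires.append(sid)

    for b in range(nb):
        brood = f"B{b + 1:02d}"
        for k in range(sizes[b]):
            rows.append(
                dict(
                    id=f"{brood}-{k + 1:02d}",
                    dam=dams[b],
                    sire=sires[b],
                    sex="F" if rng.random() < 0.5 else "M",
                    generation="F1",
                    brood=brood,
                    phantom=False,
                )
            )
    return validate_pedigree(pd.DataFrame(rows))


def _breeding_values(pedigree: pd.DataFrame, V_A: float, rng) -> np.ndarray:
    if V_A == 0:
        return np.zeros(len(pedigree))
    A = additive_relationship_matrix(pedigree).values
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(A)
        L = U * np.sqrt(np.clip(w, 0, None))
    return np.sqrt(V_A) * (L @ rng.standard_normal(len(pedigree)))


def simulate_breeding_phenotypes(
    pedigree: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw phenotypes for every non-phantom individual in the pedigree.

    Founders receive phenotypes first so that the Falconer transmission
    mode (offspring inherit m times the dam's phenotypic deviation) is
    well defined.  Offspring of the first ``n_treatment_broods`` broods
    are split evenly across the feeding treatments (labels ``trt1`` ...);
    everyone else gets the standard diet ``std``.  Concentrations are
    floored at zero and split into linamarin and lotaustralin with a
    per-individual Beta-distributed share, so total = linamarin +
    lotaustralin exactly.
    """
    ped = validate_pedigree(pedigree)
    rng = _rng(config, 1)
    n = len(ped)
    ids = list(ped["id"])
    idx = {i: k for k, i in enumerate(ids)}
    phantom = ped["phantom"].fillna(False).to_numpy(bool) if "phantom" in ped.columns \
        else np.zeros(n, bool)
    is_founder = ped["dam"].isna().to_numpy() & ped["sire"].isna().to_numpy()
    if "brood" not in ped.columns:
        ped = ped.assign(brood=ped["dam"])  # one brood per dam
    if "generation" not in ped.columns:
        ped = ped.assign(generation=np.where(is_founder, "P", "F1"))

    a = _breeding_values(ped, config.V_A, rng)
    sex_term = np.where(ped["sex"].to_numpy() == "M", config.sex_effect, 0.0)

    # treatment assignment: even within-brood splits for designated broods
    treatments = np.array(["std"] * n, dtype=object)
    trt_names = [f"trt{k + 1}" for k in range(len(config.treatment_effects))]
    trt_shift = dict(zip(trt_names, config.treatment_effects))
    trt_shift["std"] = 0.0
    if config.n_treatment_broods and config.treatment_effects:
        seen = ped["brood"].dropna().drop_duplicates().tolist()
        for brood in seen[: config.n_treatment_broods]:
            members = [k for k, v in enumerate(ped["brood"]) if v == brood]
            for j, k in enumerate(members):
                treatments[k] = trt_names[j % len(trt_names)]
    trt_term = np.array([trt_shift[t] for t in treatments])

    e = rng.normal(0.0, np.sqrt(config.V_R), size=n)
    maternal = np.zeros(n)
    if config.V_mat > 0:
        dam_ids = [d for d in ped["dam"].dropna().unique()]
        u = dict(zip(dam_ids, rng.normal(0.0, np.sqrt(config.V_mat), size=len(dam_ids))))
        maternal = np.array([u.get(d, 0.0) if d is not None else 0.0
                             for d in ped["dam"].where(ped["dam"].notna(), None)])

    pheno = np.full(n, np.nan)
    # founders first
    f_mask = is_founder
    pheno[f_mask] = (config.mu + sex_term[f_mask] + a[f_mask] + e[f_mask])
    # offspring (topological order guarantees dams are done)
    for k in range(n):
        if f_mask[k]:
            continue
        mat = maternal[k]
        if config.m_transmission != 0.0:
            d = ped["dam"].iloc[k]
            if d is None or pd.isna(d) or not np.isfinite(pheno[idx[d]]):
                raise ValueError(
                    f"Falconer mode requires a phenotyped dam; {ped['id'].iloc[k]!r} lacks one"
                )
            mat = config.m_transmission * (pheno[idx[d]] - config.mu)
        pheno[k] = config.mu + sex_term[k] + trt_term[k] + a[k] + mat + e[k]

    total = np.clip(pheno, 0.0, None)
    kappa = config.share_concentration
    share = rng.beta(config.linamarin_share * kappa,
                     (1.0 - config.linamarin_share) * kappa, size=n)
    lin = share * total
    lot = total - lin
    total = lin + lot  # re-sum so the identity holds bit-exactly

    out = pd.DataFrame(
        {
            "id": ids,
            "brood": ped["brood"].to_numpy(),
            "dam": ped["dam"].to_numpy(),
            "sire": ped["sire"].to_numpy(),
            "sex": ped["sex"].to_numpy(),
            "generation": ped["generation"].to_numpy(),
            "treatment": treatments,
            "linamarin": lin,
            "lotaustralin": lot,
            "total": total,
        }
    )
    return out[~phantom].reset_index(drop=True)


@dataclass
class FieldDistribution:
    """Right-skewed nonnegative law for wild-caught toxin concentrations,
    parameterized by its mean and SD with an optional point mass at zero
    for below-detection samples."""

    dist: str = "gamma"
    mean: float = 1.064
    sd: float = 0.709
    zero_fraction: float = 0.0
    linamarin_share: float = 0.747
    share_concentration: float = 50.0

    def __post_init__(self):
        if self.dist not in ("gamma", "lognormal"):
            raise ValueError("dist must be 'gamma' or 'lognormal'")
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("mean and sd must be positive")
        if not 0 <= self.zero_fraction <= 1:
            raise ValueError("zero_fraction must be in [0, 1]")


def simulate_field_population(
    n: int, shape_params: FieldDistribution, seed: int, population: str = "pop"
) -> pd.DataFrame:
    """Simulate per-individual total/linamarin/lotaustralin concentrations
    for one wild population."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(shape_params, FieldDistribution):
        shape_params = FieldDistribution(**dict(shape_params))
    p = shape_params
    rng = np.random.default_rng([int(seed), 2])
    if p.dist == "gamma":
        shape = p.mean**2 / p.sd**2
        scale = p.sd**2 / p.mean
        total = rng.gamma(shape, scale, size=n)
    else:
        s2 = np.log1p(p.sd**2 / p.mean**2)
        total = rng.lognormal(np.log(p.mean) - s2 / 2.0, np.sqrt(s2), size=n)
    if p.zero_fraction > 0:
        total[rng.random(n) < p.zero_fraction] = 0.0
    share = rng.beta(p.linamarin_share * p.share_concentration,
                     (1 - p.linamarin_share) * p.share_concentration, size=n)
    lin = share * total
    lot = total - lin
    return pd.DataFrame(
        {
            "id": [f"{population}-{k + 1:03d}" for k in range(n)],
            "population": population,
            "linamarin": lin,
            "lotaustralin": lot,
            "total": lin + lot,
        }
    )


def simulate_hostplants(
    site_means: Mapping, n_per_site, seed: int
) -> pd.DataFrame:
    """Simulate leaf-sample total cyanogen content (ug/mg) per group.

    ``site_means`` maps a group key to ``(mean, sd)``; a string key is
    written to a ``site`` column, a 2-tuple key to ``origin`` and
    ``treatment`` columns (for the full-factorial greenhouse design).
    ``n_per_site`` is an int applied to every group or a mapping keyed
    like ``site_means``.
    """
    rng = np.random.default_rng([int(seed), 3])
    frames = []
    for key, (mean, sd) in site_means.items():
        if mean < 0:
            raise ValueError("site means must be nonnegative")
        if sd < 0:
            raise ValueError("site SDs must be nonnegative")
        n = n_per_site[key] if isinstance(n_per_site, Mapping) else int(n_per_site)
        if sd == 0 or mean == 0:
            vals = np.full(n, float(mean))
        else:
            vals = rng.gamma(mean**2 / sd**2, sd**2 / mean, size=n)
        d = pd.DataFrame({"total_cyanogens_ug_mg": vals})
        if isinstance(key, tuple):
            d.insert(0, "origin", key[0])
            d.insert(1, "treatment", key[1])
        else:
            d.insert(0, "site", key)
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", [f"plant-{k + 1:03d}" for k in range(len(out))])
    return out
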