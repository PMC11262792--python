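"""Synthetic fixtures with known ground truth.

Three generators emulate the study's data layers without any download:
UTR sets with seed sites planted at known positions and types, cohort
expression/phenotype tables with planted per-trait effect sizes and
confounder-proxy miRNAs, and qPCR Ct tables with planted group fold
changes and injected outliers. Every generator is a pure function of its
arguments plus the seed, and emits a truth object sufficient to score any
downstream module.

Planted sites are flanked by deterministic guard bases chosen so that no
higher-priority pairing mode can form in the same seed register: the
planted type is exactly the label the scanner must report. Background is
i.i.d. with adjustable GC content (no dinucleotide structure), so
additional background motif occurrences are possible and legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seedsites import SiteType, seed_motifs
from .seqio import RNA_TO_DNA_PAIR, MatureMiRNA, UTRRecord

# ---------------------------------------------------------------------------
# planted UTRs


@dataclass(frozen=True)
class PlantedSite:
    utr_id: str
    mirna_id: str
    site_type: str
    start: int


@dataclass(frozen=True)
class PlantedSites:
    sites: tuple[PlantedSite, ...]
    seed: int


def _guard_bases(mirna: MatureMiRNA, mode: SiteType) -> tuple[Optional[set], Optional[set]]:
    """(left, right) sets of bases a guard position must avoid, or None if unneeded."""
    comp_nt8 = RNA_TO_DNA_PAIR[mirna.sequence[7]]
    comp_nt2 = RNA_TO_DNA_PAIR[mirna.sequence[1]]
    if mode is SiteType.MER8:
        return None, None
    if mode is SiteType.MER7_M8:
        return None, {"A"}
    if mode is SiteType.MER7_A1:
        return {comp_nt8}, None
    if mode is SiteType.MER6:
        return {comp_nt8}, {"A"}
    return None, {comp_nt2}  # offset-6mer


def _pick_guard(avoid: set) -> str:
    for b in "CGT":
        if b not in avoid:
            return b
    raise AssertionError("unreachable: avoid set cannot cover C, G and T")


def gen_utrs(
    n: int,
    length: int,
    gc: float = 0.4,
    plants: Sequence[tuple[int, MatureMiRNA, Union[SiteType, str], int]] = (),
    seed: int = 0,
) -> tuple[list[UTRRecord], PlantedSites]:
    """*n* random UTRs of *length* nt with seed sites spliced in.

    *plants* is a list of (utr_index, mirna, site_type, position); the mode
    motif is placed at *position* with one guard base on each side so the
    planted locus carries exactly the requested highest-priority label.
    Plants on one UTR must not overlap (guards included) and must leave one
    nt of margin to the UTR boundaries.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValidationError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = [
        list(rng.choice(list("ACGT"), size=length, p=p)) for _ in range(n)
    ]
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth = []
    for utr_idx, mirna, mode, pos in plants:
        mode = SiteType.from_label(mode) if isinstance(mode, str) else mode
        motif = seed_motifs(mirna)[mode]
        span = (pos - 1, pos + len(motif) + 1)  # guards included
        if not (0 <= utr_idx < n):
            raise ValidationError(f"plant refers to UTR index {utr_idx} (n={n})")
        if span[0] < 0 or span[1] > length:
            raise ValidationError(
                f"plant at {pos} (+guards) does not fit within UTR length {length}"
            )
        for other in occupied.get(utr_idx, []):
            if span[0] < other[1] and other[0] < span[1]:
                raise ValidationError(f"overlapping plants on UTR {utr_idx}")
        occupied.setdefault(utr_idx, []).append(span)
        seq = seqs[utr_idx]
        seq[pos : pos + len(motif)] = list(motif)
        left_avoid, right_avoid = _guard_bases(mirna, mode)
        if left_avoid is not None:
            seq[pos - 1] = _pick_guard(left_avoid)
        if right_avoid is not None:
            seq[pos + len(motif)] = _pick_guard(right_avoid)
        truth.append(
            PlantedSite(
                utr_id=f"utr{utr_idx:04d}", mirna_id=mirna.id,
                site_type=mode.label, start=pos,
            )
        )
    utrs = [UTRRecord(id=f"utr{i:04d}", sequence="".join(s)) for i, s in enumerate(seqs)]
    return utrs, PlantedSites(sites=tuple(truth), seed=seed)


def random_mirna(rng: np.random.Generator, mirna_id: str, length: int = 22) -> MatureMiRNA:
    """One random mature miRNA (uniform bases) for simulation studies."""
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return MatureMiRNA(id=mirna_id, sequence=seq, species="sim")


# ---------------------------------------------------------------------------
# cohort with planted effects

#: per-trait residual noise scales (units of the trait), multiplied by noise_sd
TRAIT_NOISE = {"HbA1c": 0.5, "glucose": 12.0, "insulin": 4.0, "triglycerides": 30.0}


@dataclass(frozen=True)
class CohortTruth:
    effects: Mapping[tuple[str, str], float]  # (mirna, response) -> true beta5
    confounder_proxies: tuple[str, ...]
    expression_means: Mapping[str, float]
    seed: int


def _z(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def gen_cohort(
    n_samples: int = 500,
    n_mirnas: int = 200,
    effects: Optional[Mapping[tuple[str, str], float]] = None,
    confounder_proxies: Sequence[str] = (),
    noise_sd: float = 1.0,
    prevalence: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Cohort expression matrix + phenotype table with planted effects.

    miRNAs are named 'sim-miR-000'...; *effects* maps (mirna, response) to
    the true per-log2-unit effect. Responses: HbA1c, glucose, insulin,
    triglycerides (linear, Gaussian noise) and T2D (logistic link, intercept
    centred to hit *prevalence*). Covariates echo the cohort design: age
    20-70 y, BMI 32-85 kg/m2, sex 0/1, NAS 0-7 (driven by BMI). miRNAs in
    *confounder_proxies* track age instead of being independent.
    """
    if n_samples < 20:
        raise ValidationError("gen_cohort requires n_samples >= 20")
    effects = dict(effects or {})
    names = [f"sim-miR-{i:03d}" for i in range(n_mirnas)]
    known = set(names)
    for (m, resp), _beta in effects.items():
        if m not in known:
            raise ValidationError(f"effect refers to unknown miRNA {m!r}")
        if resp not in set(TRAIT_NOISE) | {"T2D"}:
            raise ValidationError(f"effect refers to unknown response {resp!r}")
    bad = [m for m in confounder_proxies if m not in known]
    if bad:
        raise ValidationError(f"confounder proxies not in miRNA set: {bad}")

    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    age = rng.uniform(20, 70, n_samples)
    sex = rng.integers(0, 2, n_samples).astype(float)
    bmi = rng.uniform(32, 85, n_samples)
    nas = np.clip(np.rint(3.0 + 1.2 * _z(bmi) + rng.normal(0, 1.2, n_samples)), 0, 7)

    mu = {m: float(rng.uniform(4, 9)) for m in names}
    expr = {}
    proxies = set(confounder_proxies)
    for m in names:
        if m in proxies:
            expr[m] = mu[m] + 1.5 * _z(age) + rng.normal(0, 0.6, n_samples)
        else:
            expr[m] = mu[m] + rng.normal(0, 1.2, n_samples)
    expr_df = pd.DataFrame(expr, index=samples).T  # miRNAs x samples

    def planted(resp: str) -> np.ndarray:
        total = np.zeros(n_samples)
        for (m, r), beta in effects.items():
            if r == resp:
                total += beta * (expr[m] - mu[m])
        return total

    pheno = pd.DataFrame(index=samples)
    pheno["age"] = age
    pheno["sex"] = sex
    pheno["BMI"] = bmi
    pheno["NAS"] = nas.astype(int)
    # Continuous traits carry no direct age/BMI terms: the confounder models
    # condition on HbA1c, and an age/BMI parent of HbA1c would make it a
    # collider that induces age/BMI associations for miRNAs planted as
    # unconfounded, contradicting the emitted truth. Age/BMI structure
    # enters via the T2D response, the NAS~BMI link and the proxy miRNAs.
    base = {
        "HbA1c": 5.8 + 0.12 * (sex - 0.5),
        "glucose": 105 + 3 * (sex - 0.5),
        "insulin": 18 + 1.5 * (sex - 0.5),
        "triglycerides": 150 + 10 * (sex - 0.5),
    }
    for trait, baseline in base.items():
        pheno[trait] = baseline + planted(trait) + rng.normal(
            0, TRAIT_NOISE[trait] * noise_sd, n_samples
        )
    lp = 0.4 * _z(age) + 0.4 * _z(bmi) + 0.3 * _z(nas) + planted("T2D")
    lp = lp - lp.mean() + np.log(prevalence / (1 - prevalence))
    pheno["T2D"] = rng.binomial(1, 1 / (1 + np.exp(-lp)))

    truth = CohortTruth(
        effects=effects, confounder_proxies=tuple(sorted(proxies)),
        expression_means=mu, seed=seed,
    )
    return expr_df, pheno, truth


# ---------------------------------------------------------------------------
# Ct tables


@dataclass(frozen=True)
class CtTruth:
    group_dct: Mapping[str, float]   # intended mean dCt per group
    outlier_ids: tuple[str, ...]
    seed: int


def gen_ct(
    groups: Mapping[str, tuple[float, float, int]],
    housekeeper: tuple[float, float] = (20.0, 0.5),
    n_outliers: int = 0,
    target_assay: str = "target",
    housekeeper_assay: str = "housekeeper",
    seed: int = 0,
) -> tuple[pd.DataFrame, CtTruth]:
    """Long-format Ct table with planted group dCt means and injected outliers.

    *groups* maps a label to (mean dCt, dCt sd, n samples). Target Ct is
    the housekeeper draw plus the dCt draw, so housekeeper variation
    cancels by construction. Outliers are drawn samples whose target Ct is
    displaced by 8 SD of the pooled dCt mixture (within-group variance plus
    between-group mean spread), which puts them well outside the 3-SD
    exclusion boundary computed over all samples of the gene.
    """
    rng = np.random.default_rng(seed)
    hk_mean, hk_sd = housekeeper
    rows = []
    all_samples = []
    for g, (dct_mean, dct_sd, n) in groups.items():
        if n < 3:
            raise ValidationError(f"group {g!r} needs n >= 3")
        for i in range(n):
            sample = f"{g}_{i:02d}"
            hk_ct = rng.normal(hk_mean, hk_sd) if hk_sd > 0 else hk_mean
            dct = rng.normal(dct_mean, dct_sd) if dct_sd > 0 else dct_mean
            rows.append({"sample": sample, "assay": housekeeper_assay, "ct": hk_ct, "group": g})
            rows.append({"sample": sample, "assay": target_assay, "ct": hk_ct + dct, "group": g})
            all_samples.append(sample)
    # SD of the pooled dCt mixture: within-group variance + between-group spread
    weights = np.array([n for (_, _, n) in groups.values()], dtype=float)
    weights /= weights.sum()
    means = np.array([m for (m, _, _) in groups.values()])
    sds = np.array([s for (_, s, _) in groups.values()])
    overall = float(weights @ means)
    pooled_sd = float(np.sqrt(weights @ (sds**2 + (means - overall) ** 2)))
    outlier_ids: list[str] = []
    if n_outliers:
        if pooled_sd <= 0:
            raise ValidationError("outlier injection requires a positive dCt sd")
        outlier_ids = [str(s) for s in rng.choice(all_samples, size=n_outliers, replace=False)]
        shift = 8.0 * pooled_sd
        for row in rows:
            if row["sample"] in outlier_ids and row["assay"] == target_assay:
                row["ct"] += shift
    df = pd.DataFrame(rows, columns=["sample", "assay", "ct", "group"])
    truth = CtTruth(
        group_dct={g: v[0] for g, v in groups.items()},
        outlier_ids=tuple(sorted(outlier_ids)),
        seed=seed,
    )
    return df, truth
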