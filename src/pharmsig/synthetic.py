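"""Seeded generator of FAERS-like spontaneous report sets.

The generator produces report databases with known ground truth for
pipeline testing: each drug is mentioned independently with a
configured marginal probability, each Preferred Term occurs with a low
background probability, and selected (drug, PT) pairs carry a planted
reporting-rate multiplier ``lambda`` — reports mentioning a planted
drug experience the PT at ``lambda`` times its background rate.  With
independent, rare events the population PRR of a planted pair is close
to ``lambda`` (:func:`expected_prr` gives the exact value), so
parameter recovery can be tested end to end.

What this emulates: reports carrying one or more drugs under verbatim
name variants, sparse reaction PT lists, and demographic fields with
realistic "unknown" mass.  What it does not emulate: co-prescription
correlation between drugs (optional via ``co_mention``), reporting-
volume trends over time, and stimulated reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from pharmsig.models import ReportRecord, ReportSet, ValidationError
from pharmsig.vocabulary import DrugVocabulary

_AGE_BIN_RANGES = {
    "0-17": (0.0, 18.0),
    "18-40": (18.0, 41.0),
    "41-65": (41.0, 66.0),
    ">65": (66.0, 100.0),
}

# defaults emulating the demographic mix of gout-spectrum AE reports:
# male-skewed, concentrated in middle and old age, with a substantial
# missing-data mass, US-heavy reporter base
DEFAULT_SEX_DIST = {"male": 0.55, "female": 0.35, "unknown": 0.10}
DEFAULT_AGE_DIST = {"0-17": 0.02, "18-40": 0.08, "41-65": 0.35, ">65": 0.30, "missing": 0.25}
DEFAULT_COUNTRY_DIST = {"United States": 0.55, "Japan": 0.15, "Germany": 0.15, "": 0.15}


def _check_dist(name: str, dist: dict) -> None:
    if any(p < 0 or p > 1 for p in dist.values()):
        raise ValidationError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValidationError(f"{name}: probabilities must sum to 1, got {sum(dist.values())}")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic report generator.

    Parameters
    ----------
    n_reports
        Number of reports to generate.
    drug_catalog
        Vocabulary supplying canonical names, classes and synonyms.
    pt_catalog
        Preferred Terms the generator can emit (study PTs plus
        background noise PTs).
    drug_marginals
        Per-canonical probability that a report mentions the drug.
    background_event_prob
        Per-PT probability for reports without a planted drug; a single
        float applies to every PT.
    planted
        ``(canonical_name, pt, multiplier)`` triples; a report
        mentioning the drug experiences the PT at ``multiplier`` times
        its background probability (several planted drugs present: the
        largest multiplier applies, capped at probability 1).
    sex_dist, age_dist, country_dist
        Categorical demographic distributions; ``age_dist`` uses the
        overview bins plus a ``"missing"`` mass and ages are uniform
        within each bin; the empty-string country key means missing.
    synonym_noise
        Probability a mention is rendered as a non-canonical synonym or
        case variant instead of the canonical spelling.
    duplicate_case_prob
        Probability a case is submitted twice (an extra version-1
        report preceding the retained version 2), for exercising
        deduplication.
    seed
        RNG seed; generation is deterministic given the config.
    """

    n_reports: int
    drug_catalog: DrugVocabulary
    pt_catalog: list[str]
    drug_marginals: dict[str, float]
    background_event_prob: float | dict[str, float] = 0.002
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    sex_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_DIST))
    age_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    country_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_DIST))
    synonym_noise: float = 0.3
    duplicate_case_prob: float = 0.0
    seed: int = 0

    def background_prob(self, pt: str) -> float:
        if isinstance(self.background_event_prob, dict):
            return self.background_event_prob[pt]
        return float(self.background_event_prob)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValidationError("n_reports must be >= 0")
        if not 0 <= self.synonym_noise <= 1:
            raise ValidationError("synonym_noise must lie in [0, 1]")
        if not 0 <= self.duplicate_case_prob <= 1:
            raise ValidationError("duplicate_case_prob must lie in [0, 1]")
        unknown = set(self.drug_marginals) - set(self.drug_catalog.canonical_names)
        if unknown:
            raise ValidationError(f"drug_marginals for unknown drugs: {sorted(unknown)}")
        if any(not 0 <= p <= 1 for p in self.drug_marginals.values()):
            raise ValidationError("drug marginals must lie in [0, 1]")
        if sum(self.drug_marginals.values()) == 0 and self.n_reports > 0:
            raise ValidationError("at least one drug marginal must be positive")
        for pt in self.pt_catalog:
            p = self.background_prob(pt)
            if not 0 <= p <= 1:
                raise ValidationError(f"background probability for {pt!r} outside [0, 1]")
        for drug, pt, lam in self.planted:
            if drug not in self.drug_catalog:
                raise ValidationError(f"planted pair references unknown drug {drug!r}")
            if pt not in self.pt_catalog:
                raise ValidationError(f"planted pair references unknown PT {pt!r}")
            if lam < 0:
                raise ValidationError(f"planted multiplier for ({drug}, {pt}) is negative")
            if lam * self.background_prob(pt) > 1:
                raise ValidationError(
                    f"planted pair ({drug}, {pt}): lambda x background exceeds 1"
                )
        _check_dist("sex_dist", self.sex_dist)
        _check_dist("age_dist", self.age_dist)
        _check_dist("country_dist", self.country_dist)
        if set(self.sex_dist) - {"male", "female", "unknown"}:
            raise ValidationError("sex_dist keys must be male/female/unknown")
        bad_bins = set(self.age_dist) - (set(_AGE_BIN_RANGES) | {"missing"})
        if bad_bins:
            raise ValidationError(f"unknown age_dist bins: {sorted(bad_bins)}")


def _sample_categorical(rng: np.random.Generator, dist: dict, size: int) -> list:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def _mention_variants(vocab: DrugVocabulary, canonical: str) -> list[str]:
    """Non-canonical renderings of a drug: synonyms and case variants."""
    entry = next(e for e in vocab.entries if e.canonical == canonical)
    variants = list(entry.synonyms)
    variants.append(canonical.upper())
    if canonical.upper() != canonical:
        variants.append(canonical.lower() if canonical.lower() != canonical else canonical.title())
    return variants


def generate_reports(config: SyntheticConfig) -> ReportSet:
    """Generate a ReportSet according to ``config``; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = [d for d in config.drug_catalog.canonical_names if d in config.drug_marginals]
    probs = np.array([config.drug_marginals[d] for d in drugs], dtype=float)

    if n == 0:
        return ReportSet(records=[], provenance="synthetic")

    # drug presence: independent Bernoulli per drug; rows with no drug
    # are resampled so the >=1-drug invariant holds without a filler
    # drug distorting the marginals
    presence = rng.random((n, len(drugs))) < probs
    empty = ~presence.any(axis=1)
    while empty.any():
        presence[empty] = rng.random((int(empty.sum()), len(drugs))) < probs
        empty = ~presence.any(axis=1)

    # PT occurrence: per-report probability is background x (largest
    # planted multiplier among drugs present), capped at 1
    planted_by_pt: dict[str, list[tuple[int, float]]] = {}
    for drug, pt, lam in config.planted:
        if drug in drugs:
            planted_by_pt.setdefault(pt, []).append((drugs.index(drug), lam))
    pt_occurrence = {}
    for pt in config.pt_catalog:
        base = config.background_prob(pt)
        mult = np.ones(n)
        for col, lam in planted_by_pt.get(pt, []):
            has = presence[:, col]
            mult[has] = np.maximum(mult[has], lam)
        pt_occurrence[pt] = rng.random(n) < np.minimum(1.0, base * mult)

    sexes = _sample_categorical(rng, config.sex_dist, n)
    age_bins = _sample_categorical(rng, config.age_dist, n)
    age_uniform = rng.random(n)
    countries = _sample_categorical(rng, config.country_dist, n)
    noise_draw = rng.random(presence.sum())
    variant_pick = rng.integers(0, 2**31 - 1, presence.sum())
    dup_draw = rng.random(n)

    variants_cache = {d: _mention_variants(config.drug_catalog, d) for d in drugs}

    records: list[ReportRecord] = []
    mention_i = 0
    for i in range(n):
        mentions = []
        for j, d in enumerate(drugs):
            if not presence[i, j]:
                continue
            if noise_draw[mention_i] < config.synonym_noise:
                opts = variants_cache[d]
                mentions.append(opts[variant_pick[mention_i] % len(opts)])
            else:
                mentions.append(d)
            mention_i += 1
        pts = tuple(pt for pt in config.pt_catalog if pt_occurrence[pt][i])
        bin_label = age_bins[i]
        if bin_label == "missing":
            age = None
        else:
            lo, hi = _AGE_BIN_RANGES[bin_label]
            age = float(lo + age_uniform[i] * (hi - lo))
        country = countries[i] or None
        case_id = f"C{i:07d}"
        final_version = 2 if dup_draw[i] < config.duplicate_case_prob else 1
        if final_version == 2:
            records.append(
                ReportRecord(
                    report_id=f"R{i:07d}v1",
                    case_id=case_id,
                    version=1,
                    sex=sexes[i],
                    age_years=age,
                    country=country,
                    drug_mentions=tuple(mentions),
                    reaction_pts=pts[:-1] if len(pts) > 1 else pts,
                )
            )
        records.append(
            ReportRecord(
                report_id=f"R{i:07d}",
                case_id=case_id,
                version=final_version,
                sex=sexes[i],
                age_years=age,
                country=country,
                drug_mentions=tuple(mentions),
                reaction_pts=pts,
            )
        )
    return ReportSet(records=records, provenance=f"synthetic(seed={config.seed})")


def expected_prr(config: SyntheticConfig, drug: str, pt: str) -> float:
    """Exact population PRR of a (drug, PT) pair under the generator.

    Computed from the config's joint probabilities assuming independent
    drug presence: conditioning on the target drug being present or
    absent, the event probability is averaged over the presence of the
    other planted drugs for the PT.  For a single planted pair with a
    rare event this reduces to ``lambda`` exactly.  The >=1-drug
    resampling perturbs marginals only through reports with no drug at
    all, which is negligible whenever some drugs are common.
    """
    if drug not in config.drug_catalog:
        raise KeyError(f"unknown drug {drug!r}")
    base = config.background_prob(pt)
    if base == 0:
        raise ValueError(f"background probability of {pt!r} is zero; PRR undefined")
    planted = [(d, lam) for d, p, lam in config.planted if p == pt]
    lam_self = dict(planted).get(drug, 1.0)
    others = [(d, lam) for d, lam in planted if d != drug]

    def rate(target_present: bool) -> float:
        # average min(1, base * max multiplier) over presence subsets of
        # the other planted drugs
        total = 0.0
        for mask in range(2 ** len(others)):
            p_subset = 1.0
            mult = lam_self if target_present else 1.0
            for k, (d, lam) in enumerate(others):
                pd = config.drug_marginals.get(d, 0.0)
                if mask >> k & 1:
                    p_subset *= pd
                    mult = max(mult, lam)
                else:
                    p_subset *= 1.0 - pd
            total += p_subset * min(1.0, base * mult)
        return total

    with_drug = rate(True)
    without_drug = rate(False)
    if without_drug == 0:
        return math.inf
    return with_drug / without_drug
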