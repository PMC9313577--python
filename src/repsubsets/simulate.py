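"""Synthetic repertoires and cohorts with the statistical structure the
analysis assumes — the package's ground-truth source.

The study's raw data (flow cytometry events and immunoSEQ exports) are not
deposited, so every pipeline stage is exercised on synthetic data that
emulates the study's structure:

* repertoires with heavy-tailed clone-size distributions at the observed
  scales (hundreds of unique clonotypes in stem-cell-memory samples, tens of
  thousands in naive samples), with paired nonproductive rearrangements;
* subset families with *constructed* (exact, not sampled) shared-clonotype
  fractions, so overlap ground truth is noiseless and estimator error can be
  separated from generator error — shared clones share their nonproductive
  partners (common clonal origin), private clones never do;
* donor cohorts whose subset mixtures drift with age (naive declining,
  memory rising), with tissue-specific Ki67 turnover rates, an age-declining
  CD21+ fraction in naive cells (reaching zero after age 50 in the CD4
  compartment), and a CD21+ memory fraction per tissue/compartment.

Sequences are structurally valid CDR3 placeholders (in-frame, stop-free for
productive records), not models of V(D)J recombination biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .exceptions import InfeasibleSpecError, ValidationError
from .phenotyping import SUBSETS
from .records import (DEFAULT_IDENTITY, ClonotypeRecord, Frame, RepLabel,
                      Repertoire)

_BASES = np.array(list("ACGT"))
_ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
_STOP_CODONS = set(standard_dna_table.stop_codons)
_SENSE_CODONS = np.array([c for c in _ALL_CODONS if c not in _STOP_CODONS])
_SENSE_AA = np.array([standard_dna_table.forward_table[c]
                      for c in _SENSE_CODONS])


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------

_STOP_LIST = sorted(_STOP_CODONS)


def _productive_cdr3s(rng: np.random.Generator, n: int,
                      codon_range: tuple[int, int],
                      used: set) -> list[tuple[str, str]]:
    """``n`` unique in-frame, stop-free (nt, aa) CDR3 pairs."""
    lo, hi = codon_range
    n_codons = len(_SENSE_CODONS)
    out: list[tuple[str, str]] = []
    while len(out) < n:
        want = n - len(out)
        lengths = rng.integers(lo, hi + 1, size=want)
        idx_mat = rng.integers(0, n_codons, size=(want, hi))
        for r in range(want):
            idx = idx_mat[r, :lengths[r]]
            nt = "".join(_SENSE_CODONS[idx])
            if nt in used:
                continue
            used.add(nt)
            out.append((nt, "".join(_SENSE_AA[idx])))
    return out


def _nonproductive_cdr3(rng: np.random.Generator,
                        codon_range: tuple[int, int], used: set) -> str:
    """One unique out-of-frame or stop-codon-bearing CDR3."""
    lo, hi = codon_range
    while True:
        draws = rng.integers(0, 2 ** 30, size=6)
        length = lo + int(draws[0]) % (hi + 1 - lo)
        idx = rng.integers(0, len(_SENSE_CODONS), size=length)
        codons = list(_SENSE_CODONS[idx])
        if draws[1] % 2:        # frameshift: length not divisible by 3
            n_extra = 1 + int(draws[2]) % 2
            extra = "".join(_BASES[int(draws[3 + i]) % 4]
                            for i in range(n_extra))
            nt = "".join(codons) + extra
        else:                   # in-frame premature stop
            codons[int(draws[2]) % length] = _STOP_LIST[int(draws[3]) % 3]
            nt = "".join(codons)
        if nt not in used:
            used.add(nt)
            return nt


def _gene_calls(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    v = np.char.add("TRAV", rng.integers(1, 42, size=n).astype(str))
    j = np.char.add("TRAJ", rng.integers(1, 62, size=n).astype(str))
    return v, j


# ---------------------------------------------------------------------------
# single repertoire
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepertoireSpec:
    """Recipe for one synthetic repertoire.

    ``clone_size_law`` draws template counts per clone: ``zipf(exponent)``
    for heavy-tailed clonal expansions (smaller exponent = more clonal),
    ``geometric(p)``, or ``uniform`` (all clones at ``uniform_count``).
    When ``n_templates_target`` is set, counts are 1 + a multinomial spread
    of the remaining templates over clones weighted by the law, so the total
    matches the target exactly while every clone keeps >= 1 template.
    ``nonproductive_rate`` is the probability that a clone carries a paired
    nonproductive rearrangement on its second TCRα locus.
    """

    n_unique: int
    label: RepLabel = RepLabel()
    clone_size_law: str = "zipf"
    zipf_exponent: float = 2.5
    geometric_p: float = 0.5
    uniform_count: int = 1
    n_templates_target: Optional[int] = None
    codon_range: tuple[int, int] = (8, 15)
    nonproductive_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValidationError("n_unique must be >= 1")
        if self.clone_size_law not in ("zipf", "geometric", "uniform"):
            raise ValidationError(
                f"unknown clone_size_law {self.clone_size_law!r}")
        if self.clone_size_law == "zipf" and self.zipf_exponent <= 1:
            raise ValidationError("zipf exponent must be > 1")
        if not 0 <= self.nonproductive_rate <= 1:
            raise ValidationError("nonproductive_rate must be in [0,1]")
        lo, hi = self.codon_range
        if not (2 <= lo <= hi):
            raise ValidationError("codon_range must satisfy 2 <= lo <= hi")
        if (self.n_templates_target is not None
                and self.n_templates_target < self.n_unique):
            raise InfeasibleSpecError(
                "n_templates_target smaller than n_unique")
        # a loose sequence-space check; the space is astronomically large
        # for any realistic codon range, so only pathological specs trip it
        if self.n_unique > 61 ** lo:
            raise InfeasibleSpecError(
                f"n_unique={self.n_unique} exceeds the sequence space of "
                f"{lo}-codon CDR3s")


def _draw_counts(rng: np.random.Generator, spec: RepertoireSpec) -> np.ndarray:
    n = spec.n_unique
    if spec.clone_size_law == "zipf":
        counts = np.minimum(rng.zipf(spec.zipf_exponent, size=n), 10 ** 6)
    elif spec.clone_size_law == "geometric":
        counts = rng.geometric(spec.geometric_p, size=n)
    else:
        counts = np.full(n, spec.uniform_count)
    counts = counts.astype(np.int64)
    if spec.n_templates_target is not None:
        weights = counts / counts.sum()
        counts = 1 + rng.multinomial(spec.n_templates_target - n, weights)
    return counts


def generate_repertoire(spec: RepertoireSpec,
                        rng: np.random.Generator | None = None) -> Repertoire:
    """One synthetic repertoire: productive clonotypes plus their paired
    nonproductive rearrangements (same clone, hence same template count).

    Deterministic given ``spec.seed`` (or the supplied generator).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    used: set[str] = set()
    seqs = _productive_cdr3s(rng, spec.n_unique, spec.codon_range, used)
    counts = _draw_counts(rng, spec)
    v, j = _gene_calls(rng, spec.n_unique)
    partner = rng.random(spec.n_unique) < spec.nonproductive_rate
    records = []
    for i, (nt, aa) in enumerate(seqs):
        records.append(ClonotypeRecord(
            cdr3_nt=nt, templates=int(counts[i]), v_gene=str(v[i]),
            j_gene=str(j[i]), cdr3_aa=aa, frame=Frame.productive))
        if partner[i]:
            records.append(ClonotypeRecord(
                cdr3_nt=_nonproductive_cdr3(rng, spec.codon_range, used),
                templates=int(counts[i]), v_gene=str(v[i]), j_gene=str(j[i]),
                cdr3_aa="", frame=Frame.nonproductive))
    return Repertoire.from_records(records, label=spec.label)


# ---------------------------------------------------------------------------
# subset family with constructed overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetFamilySpec:
    """Recipe for a family of subset repertoires with planted overlap.

    ``shared_fraction[(a, b)]`` is the fraction of the *smaller* of the two
    subsets' clonotypes drawn from a pool common to exactly that pair; the
    construction is exact at the clonotype-set level, so full-set overlaps
    carry no sampling noise.  Unlisted pairs share nothing.
    """

    subsets: Mapping[str, RepertoireSpec]
    shared_fraction: Mapping[tuple[str, str], float]
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, frac in self.shared_fraction.items():
            if not 0 <= frac <= 1:
                raise ValidationError(
                    f"shared fraction for {pair} must be in [0,1]")
            a, b = pair
            if a not in self.subsets or b not in self.subsets or a == b:
                raise ValidationError(f"bad subset pair {pair}")

    def shared_count(self, a: str, b: str) -> int:
        frac = self.shared_fraction.get((a, b),
                                        self.shared_fraction.get((b, a), 0.0))
        r_min = min(self.subsets[a].n_unique, self.subsets[b].n_unique)
        return int(round(frac * r_min))


def generate_subset_family(spec: SubsetFamilySpec) -> list[Repertoire]:
    """Synthetic subset repertoires whose pairwise shared unique-clonotype
    counts match the spec exactly, with shared clones carrying identical
    nonproductive partners in both repertoires.

    Raises :class:`InfeasibleSpecError` when a subset's pairwise sharing
    obligations exceed its own size.
    """
    names = list(spec.subsets)
    rng = np.random.default_rng(spec.seed)
    shared = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            s = spec.shared_count(a, b)
            if s:
                shared[(a, b)] = s
    owed = {n: sum(s for pair, s in shared.items() if n in pair)
            for n in names}
    for n in names:
        if owed[n] > spec.subsets[n].n_unique:
            raise InfeasibleSpecError(
                f"subset {n!r} owes {owed[n]} shared clonotypes but has "
                f"only {spec.subsets[n].n_unique}")

    # one global clone pool: (nt, aa, v, j, nonproductive partner or None)
    used: set[str] = set()
    codon_range = next(iter(spec.subsets.values())).codon_range
    np_rate = float(np.mean([s.nonproductive_rate
                             for s in spec.subsets.values()]))

    def make_clones(n: int) -> list[tuple]:
        seqs = _productive_cdr3s(rng, n, codon_range, used)
        v, j = _gene_calls(rng, n)
        has_partner = rng.random(n) < np_rate
        clones = []
        for i, (nt, aa) in enumerate(seqs):
            part = (_nonproductive_cdr3(rng, codon_range, used)
                    if has_partner[i] else None)
            clones.append((nt, aa, str(v[i]), str(j[i]), part))
        return clones

    membership: dict[str, list[tuple]] = {n: [] for n in names}
    for (a, b), s in shared.items():
        pool = make_clones(s)
        membership[a].extend(pool)
        membership[b].extend(pool)
    for n in names:
        membership[n].extend(
            make_clones(spec.subsets[n].n_unique - owed[n]))

    reps = []
    for n in names:
        sub = spec.subsets[n]
        clones = membership[n]
        counts = _draw_counts(rng, sub)
        records = []
        for i, (nt, aa, v, j, part) in enumerate(clones):
            records.append(ClonotypeRecord(
                cdr3_nt=nt, templates=int(counts[i]), v_gene=v, j_gene=j,
                cdr3_aa=aa, frame=Frame.productive))
            if part is not None:
                records.append(ClonotypeRecord(
                    cdr3_nt=part, templates=int(counts[i]), v_gene=v,
                    j_gene=j, cdr3_aa="", frame=Frame.nonproductive))
        label = (sub.label if sub.label.subset == n
                 else replace(sub.label, subset=n))
        # keys are unique by construction (one global sequence set)
        reps.append(Repertoire._trusted(label, tuple(records),
                                        DEFAULT_IDENTITY))
    return reps


def default_family_spec(compartment: str = "CD4", seed: int = 0,
                        scale: float = 1.0) -> SubsetFamilySpec:
    """The default synthetic subset family: unique-clonotype scales matching
    the study's sequencing yields (SCM in the hundreds, naive in the tens of
    thousands), memory subsets more clonal (smaller zipf exponent), and a
    planted overlap ordering with resting↔effector memory pairs sharing the
    most and naive↔memory pairs sharing almost nothing.

    ``scale`` shrinks every subset proportionally for quick demos.
    """
    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    def sub(subset: str, n_unique: int, a: float) -> RepertoireSpec:
        return RepertoireSpec(
            n_unique=n_unique, zipf_exponent=a,
            label=RepLabel(donor_id="sim", compartment=compartment,
                           subset=subset, tissue="MLN"),
            seed=seed)

    if compartment == "CD4":
        subsets = {"naive": sub("naive", n(40_000), 3.5),
                   "SCM": sub("SCM", n(500), 3.5),
                   "CM": sub("CM", n(30_000), 2.5),
                   "EM": sub("EM", n(20_000), 2.0)}
        sharing = {("CM", "EM"): 0.30, ("SCM", "CM"): 0.15,
                   ("SCM", "EM"): 0.08, ("naive", "SCM"): 0.01,
                   ("naive", "CM"): 0.01, ("naive", "EM"): 0.01}
    elif compartment == "CD8":
        subsets = {"naive": sub("naive", n(30_000), 3.5),
                   "SCM": sub("SCM", n(300), 3.5),
                   "EM": sub("EM", n(6_000), 1.8),
                   "EMRA": sub("EMRA", n(2_500), 2.2)}
        sharing = {("EM", "EMRA"): 0.35, ("SCM", "EM"): 0.12,
                   ("SCM", "EMRA"): 0.06, ("naive", "SCM"): 0.005,
                   ("naive", "EM"): 0.005, ("naive", "EMRA"): 0.005}
    else:
        raise ValidationError(f"unknown compartment {compartment!r}")
    return SubsetFamilySpec(subsets=subsets, shared_fraction=sharing,
                            seed=seed)


# ---------------------------------------------------------------------------
# donor cohorts
# ---------------------------------------------------------------------------

#: (tissue, compartment) -> (mixture at age 0, mixture at age 67) over
#: (naive, SCM, CM, EM, EMRA); interpolated linearly in age and renormalized.
_MIXTURES: dict[tuple[str, str], tuple[tuple[float, ...], tuple[float, ...]]] = {
    ("blood", "CD4"): ((0.70, 0.06, 0.12, 0.10, 0.02),
                       (0.25, 0.02, 0.32, 0.30, 0.11)),
    ("blood", "CD8"): ((0.65, 0.05, 0.08, 0.10, 0.12),
                       (0.18, 0.02, 0.08, 0.25, 0.47)),
    ("MLN", "CD4"): ((0.65, 0.05, 0.18, 0.10, 0.02),
                     (0.40, 0.03, 0.27, 0.25, 0.05)),
    ("MLN", "CD8"): ((0.55, 0.04, 0.10, 0.25, 0.06),
                     (0.33, 0.02, 0.10, 0.40, 0.15)),
    ("spleen", "CD4"): ((0.30, 0.03, 0.33, 0.28, 0.06),
                        (0.08, 0.01, 0.38, 0.40, 0.13)),
    ("spleen", "CD8"): ((0.15, 0.02, 0.12, 0.40, 0.31),
                        (0.02, 0.01, 0.10, 0.50, 0.37)),
    ("ileum", "CD4"): ((0.15, 0.01, 0.12, 0.62, 0.10),
                       (0.02, 0.005, 0.045, 0.83, 0.10)),
    ("ileum", "CD8"): ((0.10, 0.01, 0.05, 0.60, 0.24),
                       (0.01, 0.005, 0.035, 0.70, 0.25)),
}

#: canonical Table-style marker profiles (CD45RA, CCR7, CD95, CD27, CD28);
#: None = heterogeneous (drawn 50/50)
_PROFILES: dict[str, tuple] = {
    "naive": (True, True, False, True, True),
    "SCM": (True, True, True, True, True),
    "CM": (False, True, False, True, True),
    "EM": (False, False, False, None, None),
    "EMRA": (True, False, False, False, False),
}

_KI67_BASE = {"naive": 0.01, "SCM": 0.08, "CM": 0.05, "EM": 0.03,
              "EMRA": 0.02}
_KI67_TISSUE = {"blood": 1.2, "MLN": 0.6, "spleen": 0.6, "ileum": 1.5}

_CD21_MEMORY = {("spleen", "CD8"): 0.227, ("spleen", "CD4"): 0.10,
                ("blood", "CD4"): 0.02, ("blood", "CD8"): 0.02,
                ("MLN", "CD4"): 0.10, ("MLN", "CD8"): 0.10,
                ("ileum", "CD4"): 0.08, ("ileum", "CD8"): 0.08}


def _cd21_naive_rate(age: float, compartment: str) -> float:
    # CD4 RTE marker vanishes after age 50 (thymic involution); CD8 declines
    # more slowly and keeps a floor
    if compartment == "CD4":
        return 0.45 * max(0.0, 1.0 - age / 50.0)
    return max(0.05, 0.45 * (1.0 - age / 90.0))


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic donor cohort.

    Mixtures interpolate between age-0 and age-67 subset compositions per
    (tissue, compartment), multiplied by a per-(donor, compartment, subset)
    log-normal random effect of scale ``donor_effect_sd`` and renormalized —
    the between-donor scatter around the age trend.  ``marker_noise`` is the
    independent per-marker flip probability applied to the phenotyping
    markers (CD45RA, CCR7, CD95, CD27, CD28, CD62L); Ki67/CD21/CD31 are
    drawn from their own per-subset rates.
    """

    n_donors: int = 12
    age_range: tuple[float, float] = (0.1, 67.0)
    tissues: tuple[str, ...] = ("blood", "MLN", "spleen", "ileum")
    compartments: tuple[str, ...] = ("CD4", "CD8")
    cells_per_group: int = 2000
    marker_noise: float = 0.02
    donor_effect_sd: float = 0.35
    ki67_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_KI67_BASE))
    cmv_adult_prevalence: float = 9 / 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValidationError("n_donors must be >= 1")
        if not 0 <= self.marker_noise <= 1:
            raise ValidationError("marker_noise must be in [0,1]")
        for subset, rate in self.ki67_rates.items():
            if not 0 <= rate <= 1:
                raise ValidationError(
                    f"ki67 rate for {subset} must be in [0,1]")


def _mixture(tissue: str, compartment: str, age: float,
             donor_mult: np.ndarray) -> np.ndarray:
    young, old = _MIXTURES[(tissue, compartment)]
    t = min(max(age / 67.0, 0.0), 1.0)
    w = (1 - t) * np.asarray(young) + t * np.asarray(old)
    w = w * donor_mult
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValidationError("subset mixture does not normalize")
    return w / total


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """A synthetic cohort as a per-cell table (one row per cell) with
    boolean marker columns, donor metadata, and a ``true_subset``
    ground-truth column.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = np.sort(rng.uniform(lo, hi, size=spec.n_donors))
    cmv = np.where(
        ages >= 18,
        rng.random(spec.n_donors) < spec.cmv_adult_prevalence,
        rng.random(spec.n_donors) < 0.1)
    donor_mult = {
        (d, comp): rng.lognormal(0.0, spec.donor_effect_sd, size=len(SUBSETS))
        for d in range(spec.n_donors) for comp in spec.compartments}

    frames = []
    for d in range(spec.n_donors):
        donor_id = f"D{d + 1:02d}"
        age = float(ages[d])
        cmv_status = "positive" if cmv[d] else "negative"
        for tissue in spec.tissues:
            for comp in spec.compartments:
                w = _mixture(tissue, comp, age, donor_mult[(d, comp)])
                n_sub = rng.multinomial(spec.cells_per_group, w)
                for s_i, subset in enumerate(SUBSETS):
                    n = int(n_sub[s_i])
                    if n == 0:
                        continue
                    ra, ccr7, cd95, cd27, cd28 = _PROFILES[subset]
                    block = {
                        "CD45RA": np.full(n, ra),
                        "CCR7": np.full(n, ccr7),
                        "CD95": np.full(n, cd95),
                        "CD27": (rng.random(n) < 0.5 if cd27 is None
                                 else np.full(n, cd27)),
                        "CD28": (rng.random(n) < 0.5 if cd28 is None
                                 else np.full(n, cd28)),
                    }
                    block["CD62L"] = block["CCR7"].copy()
                    if spec.marker_noise > 0:
                        for m in ("CD45RA", "CCR7", "CD95", "CD27", "CD28",
                                  "CD62L"):
                            flip = rng.random(n) < spec.marker_noise
                            block[m] = block[m] ^ flip
                    ki67 = min(1.0, spec.ki67_rates[subset]
                               * _KI67_TISSUE[tissue])
                    block["Ki67"] = rng.random(n) < ki67
                    if subset == "naive":
                        cd21_rate = _cd21_naive_rate(age, comp)
                        cd31_rate = (max(0.3, 0.92 - 0.004 * age)
                                     if comp == "CD4" else 0.95)
                    else:
                        cd21_rate = _CD21_MEMORY[(tissue, comp)]
                        cd31_rate = 0.3
                    block["CD21"] = rng.random(n) < cd21_rate
                    block["CD31"] = rng.random(n) < cd31_rate
                    df = pd.DataFrame(block)
                    df.insert(0, "donor_id", donor_id)
                    df.insert(1, "age_years", age)
                    df.insert(2, "tissue", tissue)
                    df.insert(3, "cmv_status", cmv_status)
                    df.insert(4, "compartment", comp)
                    df["true_subset"] = subset
                    frames.append(df)
    return pd.concat(frames, ignore_index=True)
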