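"""Synthetic small RNA-seq cohort generator with known ground truth.

The generator emulates the statistical structure of a deep-sequenced tumor
miRNA cohort: a top-heavy mature-miRNA expression profile in which the five
most abundant miRNAs carry roughly half of all miRNA reads, read lengths of
13-29 nt with ~98% between 19 and 23 nt, a per-sample RNA-class composition
centred on ~61% mature miRNA / 33% intronic-intergenic / 4% hairpin
precursor / 2% snoRNA, multi-mapping across paralogous mature miRNAs,
occasional 1-mismatch alignments, clinicopathological covariates with
cohort-like marginals, and survival endpoints following a proportional
hazards model.  Expression and survival effects can be planted, and every
read's miRNA of origin is recorded, so downstream quantification and
inference can be scored against the truth.

All randomness flows from ``SimConfig.seed`` through deterministically
derived sub-streams (annotation, clinical, per-sample expression, per-run
read noise), so two runs of the same configuration are byte-identical and
technical replicates (``run_id`` 0/1) share biology but not sampling noise.
"""

from __future__ import annotations

import re
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import AnnotationSet, intergenic_gaps
from .samio import write_sam

CORE_LENGTH_RANGE = (19, 23)
READ_LENGTH_RANGE = (13, 29)

#: Cohort-like marginal frequencies for the eight clinicopathological
#: covariates tested downstream (counts out of 88 in the emulated cohort).
DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    "TNM": {"1": 10 / 88, "2": 51 / 88, "3": 27 / 88},
    "pT": {"1": 2 / 88, "2": 10 / 88, "3": 70 / 88, "4": 6 / 88},
    "pN": {"0": 61 / 88, "1": 16 / 88, "2": 11 / 88},
    "localization": {"right": 33 / 88, "transverse": 5 / 88,
                     "left": 24 / 88, "rectum": 26 / 88},
    "differentiation": {"poor": 10 / 88, "intermediate": 76 / 88,
                        "well": 2 / 88},
    "perinodal_infiltration": {"absent": 70 / 88, "present": 18 / 88},
    "vascular_invasion": {"absent": 69 / 88, "present": 19 / 88},
    "neural_infiltration": {"absent": 82 / 88, "present": 6 / 88},
}

DEFAULT_CLASS_PROPS = {
    "mature": 0.61,
    "premature": 0.04,
    "snoRNA": 0.02,
    "intronic/intergenic": 0.3295,
    "other": 0.0005,
}

_FAMILY_RE = re.compile(r"^miR-f(\d+)[a-z]$")


@dataclass(frozen=True)
class PlantedExpressionEffect:
    """Multiply the expression weight of `mirna` by `fold` in samples whose
    `covariate` equals `level`."""
    mirna: str
    covariate: str
    level: str
    fold: float


@dataclass(frozen=True)
class PlantedSurvivalEffect:
    """Log hazard ratio per unit centred log2 expression of `mirna` for the
    named endpoint ("os" or "mfs")."""
    mirna: str
    endpoint: str
    log_hr: float


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults are the emulated study conditions: 88 samples, 523 expressed
    miRNAs, top-5 share 53.7% of miRNA reads, 97.9% of read lengths in
    19-23 nt, and the median RNA-class composition above.  Sequencing depth
    defaults to 20,000 reads per sample; per-read statistical structure is
    depth-independent.
    """

    n_mirnas: int = 523
    n_clusters: int = 5
    n_samples: int = 88
    reads_per_sample: int = 20_000
    length_dist: dict[int, float] | None = None
    frac_core_length: float = 0.979
    class_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPS))
    top5_share: float = 0.537
    multimap_frac: float = 0.10
    mismatch_rate: float = 0.05
    planted_expression: tuple[PlantedExpressionEffect, ...] = ()
    planted_survival: tuple[PlantedSurvivalEffect, ...] = ()
    seed: int = 0
    # structural knobs (generator conventions, not cohort statistics)
    paralog_frac: float = 0.30
    n_snorna: int = 60
    n_misc: int = 10
    class_dispersion: float = 35.0
    decoy_rate: float = 0.02
    highmap_frac: float = 0.005
    covariates: dict[str, dict[str, float]] = field(
        default_factory=lambda: deepcopy(DEFAULT_COVARIATES))
    follow_up_days: float = 3650.0
    baseline_hazard: float = 1.6 / 3650.0
    endpoints: tuple[str, ...] = ("os", "mfs")

    def validate(self) -> None:
        total = sum(self.class_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_props sums to {total}, expected 1")
        for name in ("n_mirnas", "n_clusters", "n_samples",
                     "reads_per_sample"):
            if getattr(self, name) <= 0 and name != "n_clusters":
                raise ValueError(f"{name} must be positive")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        for name in ("frac_core_length", "top5_share", "multimap_frac",
                     "mismatch_rate", "paralog_frac", "decoy_rate",
                     "highmap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.length_dist is not None:
            s = sum(self.length_dist.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError("length_dist must sum to 1")
            lo, hi = READ_LENGTH_RANGE
            if any(not lo <= k <= hi for k in self.length_dist):
                raise ValueError("length_dist keys must lie in 13..29")

    def length_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """Read lengths and their probabilities.

        If ``length_dist`` is not given, builds a default: a peaked core
        over 19-23 nt holding ``frac_core_length`` of the mass, the
        remainder spread evenly over 13-18 and 24-29 nt.
        """
        lo, hi = READ_LENGTH_RANGE
        lengths = np.arange(lo, hi + 1)
        if self.length_dist is not None:
            probs = np.array([self.length_dist.get(int(l), 0.0)
                              for l in lengths])
            return lengths, probs
        core_lo, core_hi = CORE_LENGTH_RANGE
        core_shape = {19: 0.10, 20: 0.22, 21: 0.34, 22: 0.23, 23: 0.11}
        probs = np.zeros(len(lengths))
        for l, w in core_shape.items():
            probs[l - lo] = w * self.frac_core_length
        n_tail = (core_lo - lo) + (hi - core_hi)
        tail_p = (1.0 - self.frac_core_length) / n_tail
        for l in lengths:
            if l < core_lo or l > core_hi:
                probs[l - lo] = tail_p
        return lengths, probs / probs.sum()


def _rng(seed: int, *key: int) -> np.random.Generator:
    """A generator for one named sub-stream of the master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


# ---------------------------------------------------------------------------
# expression profile


def zipf_exponent(n_mirnas: int, top_share: float, k: int = 5) -> float:
    """Exponent of a truncated power law whose top-`k` share equals
    `top_share` over `n_mirnas` ranks."""
    if not 0 < top_share < 1:
        raise ValueError("top_share must be in (0, 1)")
    ranks = np.arange(1, n_mirnas + 1, dtype=float)

    def gap(s: float) -> float:
        w = ranks ** -s
        return w[:k].sum() / w.sum() - top_share

    uniform_share = k / n_mirnas
    if top_share <= uniform_share:
        raise ValueError("top_share below the uniform share; no power law")
    return brentq(gap, 1e-9, 16.0)


def expression_weights(n_mirnas: int, top5_share: float) -> np.ndarray:
    """Base per-miRNA expression weights (rank 1 = most expressed).

    Truncated power law with the exponent solved so the expected top-5
    share equals `top5_share`; uniform when that target is at or below the
    uniform share (only possible for very small annotations).
    """
    if n_mirnas <= 5 or top5_share <= 5 / n_mirnas:
        return np.full(n_mirnas, 1.0 / n_mirnas)
    s = zipf_exponent(n_mirnas, top5_share)
    w = np.arange(1, n_mirnas + 1, dtype=float) ** -s
    return w / w.sum()


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimConfig) -> AnnotationSet:
    """Lay out mature miRNAs inside hairpin precursors, snoRNAs and misc
    features along one synthetic chromosome.

    Clustered miRNA gene pairs are placed < 10 kb apart; paralogous
    families (the multi-mapping groups) share one mature length and are
    recognisable by their names (``miR-f012a``, ``miR-f012b``, ...).
    """
    config.validate()
    if 2 * config.n_clusters > config.n_mirnas:
        raise ValueError("cannot place clusters: 2*n_clusters > n_mirnas")
    rng = _rng(config.seed, 4)
    n = config.n_mirnas
    chrom = "chrS1"

    # paralog families of size 2-4 covering ~paralog_frac of miRNAs
    order = rng.permutation(n)
    n_grouped_target = int(round(config.paralog_frac * n))
    families: list[list[int]] = []
    pos = 0
    while pos + 2 <= n and sum(len(f) for f in families) < n_grouped_target:
        size = int(rng.integers(2, 5))
        size = min(size, n - pos)
        if size < 2:
            break
        families.append(sorted(order[pos:pos + size]))
        pos += size
    family_of = np.full(n, -1)
    for fid, members in enumerate(families):
        for m in members:
            family_of[m] = fid

    # mature lengths: paralog family members share a length so multi-mapped
    # reads fit every member identically
    length_choices = np.array([22, 23, 24, 25])
    length_probs = np.array([0.35, 0.35, 0.2, 0.1])
    mat_len = rng.choice(length_choices, size=n, p=length_probs)
    fam_len = rng.choice(length_choices, size=max(len(families), 1),
                         p=length_probs)
    grouped = family_of >= 0
    mat_len[grouped] = fam_len[family_of[grouped]]

    # cluster pairs: second member follows the first with a small gap
    cluster_second = np.zeros(n, dtype=bool)
    candidates = rng.permutation(n - 1)
    used = np.zeros(n, dtype=bool)
    placed = 0
    for i in candidates:
        if placed == config.n_clusters:
            break
        if used[i] or used[i + 1]:
            continue
        cluster_second[i + 1] = True
        used[i] = used[i + 1] = True
        placed += 1
    if placed < config.n_clusters:
        raise ValueError("could not place the requested miRNA clusters")

    names = []
    fam_letter = {fid: 0 for fid in range(len(families))}
    for i in range(n):
        fid = family_of[i]
        if fid >= 0:
            names.append(f"miR-f{fid:03d}{chr(97 + fam_letter[fid])}")
            fam_letter[fid] += 1
        else:
            names.append(f"miR-s{i:04d}")

    rows = []
    cursor = 1000
    for i in range(n):
        # non-clustered miRNA genes sit >= 10 kb apart so clustered pairs
        # are the only mature miRNAs within 10 kb of each other
        gap = int(rng.integers(200, 6000)) if cluster_second[i] \
            else int(rng.integers(10_000, 25_000))
        lead = int(rng.integers(10, 21))
        tail = int(rng.integers(35, 51))
        hp_start = cursor + gap
        m_start = hp_start + lead
        m_end = m_start + int(mat_len[i])
        hp_end = m_end + tail
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, hp_start, hp_end, strand,
                     f"pre-{names[i]}", "premature"))
        rows.append((chrom, m_start, m_end, strand, names[i], "mature"))
        cursor = hp_end
        if cluster_second[i] and m_start - rows[-4][1] >= 10_000:
            raise AssertionError("cluster pair ended up >= 10 kb apart")

    for j in range(config.n_snorna):
        gap = int(rng.integers(800, 2500))
        length = int(rng.integers(100, 151))
        start = cursor + gap
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, start, start + length, strand,
                     f"SNORD-s{j:03d}", "snoRNA"))
        cursor = start + length
    for j in range(config.n_misc):
        gap = int(rng.integers(800, 2500))
        length = int(rng.integers(80, 151))
        start = cursor + gap
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, start, start + length, strand,
                     f"MISC-s{j:03d}", "miscRNA"))
        cursor = start + length

    feats = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "name",
                       "feature_class"])
    return AnnotationSet(feats, {chrom: cursor + 5000})


def paralog_groups(annotation: AnnotationSet) -> list[list[str]]:
    """Paralogous mature-miRNA families, recovered from the naming scheme."""
    groups: dict[str, list[str]] = {}
    for name in annotation.mirna_names:
        m = _FAMILY_RE.match(name)
        if m:
            groups.setdefault(m.group(1), []).append(name)
    return [sorted(v) for _, v in sorted(groups.items())]


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    alignments: dict[str, pd.DataFrame]
    true_counts: pd.DataFrame          # miRNA x sample, reads of origin
    clinical: pd.DataFrame             # sample x covariate
    survival: pd.DataFrame             # long: sample, endpoint, time, event
    expression: pd.DataFrame           # miRNA x sample expected weights
    annotation: AnnotationSet
    config: SimConfig

    @property
    def samples(self) -> list[str]:
        return list(self.alignments)

    def write(self, outdir: str | Path) -> None:
        """Write SAM per sample plus annotation BED and truth/clinical TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, aln in self.alignments.items():
            write_sam(aln, outdir / f"{sample}.sam",
                      self.annotation.chrom_sizes, sample=sample)
        self.annotation.to_bed(outdir / "annotation.bed")
        self.true_counts.to_csv(outdir / "true_counts.tsv", sep="\t")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        self.survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)


def _allocate_levels(probs: dict[str, float], n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Exact largest-remainder allocation of `n` samples to levels,
    returned in shuffled order."""
    levels = list(probs)
    quotas = np.array([probs[l] * n for l in levels])
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quotas - base))
    base[order[:short]] += 1
    values = np.repeat(levels, base)
    return rng.permutation(values)


def generate_clinical(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config.seed, 2)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    data = {cov: _allocate_levels(levels, config.n_samples, rng)
            for cov, levels in config.covariates.items()}
    return pd.DataFrame(data, index=pd.Index(samples, name="sample"))


def _sample_weights(base_w: np.ndarray, names: Sequence[str],
                    clinical_row: pd.Series,
                    effects: Sequence[PlantedExpressionEffect]) -> np.ndarray:
    w = base_w.copy()
    idx = {n: i for i, n in enumerate(names)}
    for eff in effects:
        if eff.mirna not in idx:
            raise ValueError(f"planted effect references unknown miRNA "
                             f"{eff.mirna!r}")
        if eff.covariate not in clinical_row.index:
            raise ValueError(f"planted effect references unknown covariate "
                             f"{eff.covariate!r}")
        if clinical_row[eff.covariate] == eff.level:
            w[idx[eff.mirna]] *= eff.fold
    return w / w.sum()


def simulate_survival(x: np.ndarray, beta: float | np.ndarray,
                      rng: np.random.Generator,
                      baseline_hazard: float = 1.6 / 3650.0,
                      censor_upper: float = 3650.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) from a proportional hazards model.

    Exponential baseline with hazard `baseline_hazard`; linear predictor
    ``x @ beta`` (x is centred by the caller if desired); independent
    uniform censoring on (0, censor_upper].  With the defaults the expected
    event fraction is 1 - (1 - e^-1.6)/1.6 ~ 0.50.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and np.ndim(beta) == 0:
        x = x.T
    eta = x @ np.atleast_1d(np.asarray(beta, dtype=float))
    latent = rng.exponential(1.0, size=len(eta)) / (
        baseline_hazard * np.exp(eta))
    censor = rng.uniform(0.0, censor_upper, size=len(eta))
    time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)
    return time, event


def generate_cohort(annotation: AnnotationSet, config: SimConfig,
                    run_id: int = 0) -> Cohort:
    """Generate per-sample alignment sets, ground-truth counts, clinical
    covariates and survival outcomes.

    ``run_id`` selects the read-sampling noise stream while the biological
    layer (expression weights, class composition, clinical, survival) is
    shared, emulating technical re-sequencing of the same libraries.
    """
    config.validate()
    if len(annotation.mature) == 0:
        raise ValueError("annotation contains no mature miRNAs")

    mat = annotation.mature.reset_index(drop=True)
    names = list(mat["name"])
    n_mir = len(names)
    name_idx = {n: i for i, n in enumerate(names)}
    m_start = mat["start"].to_numpy()
    m_end = mat["end"].to_numpy()
    m_len = m_end - m_start
    m_strand = mat["strand"].to_numpy()
    chrom = mat["chrom"].to_numpy()

    pre = annotation.of_class("premature").set_index("name")
    hp_end = pre.loc[[f"pre-{n}" for n in names], "end"].to_numpy()

    sno = annotation.of_class("snoRNA").reset_index(drop=True)
    misc = annotation.of_class("miscRNA").reset_index(drop=True)
    gaps = intergenic_gaps(annotation)
    gaps = gaps[(gaps["end"] - gaps["start"]) >= 60].reset_index(drop=True)
    gap_len = (gaps["end"] - gaps["start"]).to_numpy()
    gap_p = gap_len / gap_len.sum()

    # paralog groups -> per-miRNA list of other members
    groups = paralog_groups(annotation)
    group_of = np.full(n_mir, -1)
    for gid, members in enumerate(groups):
        for m in members:
            group_of[name_idx[m]] = gid
    others: list[np.ndarray] = [np.array([], dtype=int)] * n_mir
    for gid, members in enumerate(groups):
        idxs = [name_idx[m] for m in members]
        for i in idxs:
            others[i] = np.array([j for j in idxs if j != i])
    max_others = max((len(o) for o in others), default=0)
    other_mat = np.full((n_mir, max(max_others, 1)), -1)
    for i, o in enumerate(others):
        other_mat[i, :len(o)] = o

    base_w = expression_weights(n_mir, config.top5_share)
    lengths, length_p = config.length_probs()

    clinical = generate_clinical(config)
    samples = list(clinical.index)

    class_names = list(config.class_props)
    base_props = np.array([config.class_props[c] for c in class_names])

    alignments: dict[str, pd.DataFrame] = {}
    true_counts = np.zeros((n_mir, len(samples)), dtype=int)
    weights_mat = np.zeros((n_mir, len(samples)))

    for s_idx, sample in enumerate(samples):
        rng_bio = _rng(config.seed, 0, s_idx)          # shared across runs
        rng_rd = _rng(config.seed, 1, run_id, s_idx)   # per-run noise

        w_s = _sample_weights(base_w, names, clinical.loc[sample],
                              config.planted_expression)
        weights_mat[:, s_idx] = w_s
        props_s = rng_bio.dirichlet(config.class_dispersion * base_props)

        n_reads = rng_rd.poisson(config.reads_per_sample)
        class_counts = rng_rd.multinomial(n_reads, props_s)
        counts = dict(zip(class_names, class_counts))

        parts: list[pd.DataFrame] = []
        next_id = 0

        # ---- mature miRNA reads -------------------------------------
        n_mat_reads = counts.get("mature", 0)
        per_mirna = rng_rd.multinomial(n_mat_reads, w_s)
        true_counts[:, s_idx] = per_mirna
        mi = np.repeat(np.arange(n_mir), per_mirna)
        rng_rd.shuffle(mi)
        L = rng_rd.choice(lengths, size=n_mat_reads, p=length_p)
        L = np.minimum(L, m_len[mi])  # full mature sequence at most
        span = m_len[mi] - L + 1
        off = (rng_rd.random(n_mat_reads) * span).astype(int)
        start = m_start[mi] + off
        nm = (rng_rd.random(n_mat_reads) < config.mismatch_rate).astype(int)
        rid = np.arange(next_id, next_id + n_mat_reads)
        next_id += n_mat_reads
        parts.append(pd.DataFrame({
            "read_id": rid, "chrom": chrom[mi], "start": start,
            "end": start + L, "strand": m_strand[mi], "nm": nm}))

        # extra alignments at paralogous loci; capped below 1 so every
        # family keeps uniquely-mapping reads in expectation — the ratio
        # assignment the pipeline relies on is undefined without them
        grouped_share = w_s[group_of >= 0].sum()
        p_mm = min(0.85, config.multimap_frac / grouped_share) \
            if grouped_share > 0 else 0.0
        mm = (group_of[mi] >= 0) & (rng_rd.random(n_mat_reads) < p_mm)
        for k in range(max_others):
            member = other_mat[mi, k] if max_others else np.array([])
            sel = mm & (member >= 0)
            if not sel.any():
                continue
            mj = member[sel]
            st = m_start[mj] + off[sel]
            parts.append(pd.DataFrame({
                "read_id": rid[sel], "chrom": chrom[mj], "start": st,
                "end": st + L[sel], "strand": m_strand[mj],
                "nm": nm[sel]}))

        # decoy 1-mismatch alignments elsewhere in the genome
        dec = rng_rd.random(n_mat_reads) < config.decoy_rate
        n_dec = int(dec.sum())
        if n_dec:
            g = rng_rd.choice(len(gaps), size=n_dec, p=gap_p)
            off_g = (rng_rd.random(n_dec)
                     * (gap_len[g] - L[dec])).astype(int)
            st = gaps["start"].to_numpy()[g] + off_g
            parts.append(pd.DataFrame({
                "read_id": rid[dec], "chrom": gaps["chrom"].to_numpy()[g],
                "start": st, "end": st + L[dec],
                "strand": np.where(rng_rd.random(n_dec) < 0.5, "+", "-"),
                "nm": np.ones(n_dec, dtype=int)}))

        # ---- hairpin (premature) reads ------------------------------
        n_pre = counts.get("premature", 0)
        if n_pre:
            pi = rng_rd.choice(n_mir, size=n_pre, p=w_s)
            Lp = rng_rd.choice(lengths, size=n_pre, p=length_p)
            span = hp_end[pi] - m_end[pi] - Lp + 1
            off = (rng_rd.random(n_pre) * span).astype(int)
            st = m_end[pi] + off
            rid_p = np.arange(next_id, next_id + n_pre)
            next_id += n_pre
            parts.append(pd.DataFrame({
                "read_id": rid_p, "chrom": chrom[pi], "start": st,
                "end": st + Lp, "strand": m_strand[pi],
                "nm": np.zeros(n_pre, dtype=int)}))

        # ---- snoRNA and misc reads ----------------------------------
        for cname, feats in (("snoRNA", sno), ("other", misc)):
            n_c = counts.get(cname, 0)
            if not n_c or len(feats) == 0:
                continue
            fi = rng_rd.integers(0, len(feats), size=n_c)
            Lc = rng_rd.choice(lengths, size=n_c, p=length_p)
            f_start = feats["start"].to_numpy()[fi]
            f_len = (feats["end"] - feats["start"]).to_numpy()[fi]
            off = (rng_rd.random(n_c) * (f_len - Lc + 1)).astype(int)
            st = f_start + off
            rid_c = np.arange(next_id, next_id + n_c)
            next_id += n_c
            parts.append(pd.DataFrame({
                "read_id": rid_c, "chrom": feats["chrom"].to_numpy()[fi],
                "start": st, "end": st + Lc,
                "strand": feats["strand"].to_numpy()[fi],
                "nm": np.zeros(n_c, dtype=int)}))

        # ---- intronic/intergenic reads ------------------------------
        n_int = counts.get("intronic/intergenic", 0)
        if n_int:
            Li = rng_rd.choice(lengths, size=n_int, p=length_p)
            g = rng_rd.choice(len(gaps), size=n_int, p=gap_p)
            off = (rng_rd.random(n_int) * (gap_len[g] - Li)).astype(int)
            st = gaps["start"].to_numpy()[g] + off
            rid_i = np.arange(next_id, next_id + n_int)
            next_id += n_int
            strand_i = np.where(rng_rd.random(n_int) < 0.5, "+", "-")
            parts.append(pd.DataFrame({
                "read_id": rid_i, "chrom": gaps["chrom"].to_numpy()[g],
                "start": st, "end": st + Li, "strand": strand_i,
                "nm": np.zeros(n_int, dtype=int)}))
            # a small fraction map to >= 10 repeat-like loci
            hm = rng_rd.random(n_int) < config.highmap_frac
            n_hm = int(hm.sum())
            if n_hm:
                extra = rng_rd.integers(9, 15, size=n_hm)
                rep_rid = np.repeat(rid_i[hm], extra)
                rep_L = np.repeat(Li[hm], extra)
                g2 = rng_rd.choice(len(gaps), size=len(rep_rid), p=gap_p)
                off2 = (rng_rd.random(len(rep_rid))
                        * (gap_len[g2] - rep_L)).astype(int)
                st2 = gaps["start"].to_numpy()[g2] + off2
                parts.append(pd.DataFrame({
                    "read_id": rep_rid,
                    "chrom": gaps["chrom"].to_numpy()[g2],
                    "start": st2, "end": st2 + rep_L,
                    "strand": np.where(
                        rng_rd.random(len(rep_rid)) < 0.5, "+", "-"),
                    "nm": np.zeros(len(rep_rid), dtype=int)}))

        df = pd.concat(parts, ignore_index=True)
        alignments[sample] = df.sort_values(
            ["read_id", "chrom", "start"], kind="stable",
            ignore_index=True)

    # ---- survival ----------------------------------------------------
    rng_sur = _rng(config.seed, 3)
    surv_rows = []
    for endpoint in config.endpoints:
        eta = np.zeros(len(samples))
        for eff in config.planted_survival:
            if eff.endpoint != endpoint:
                continue
            if eff.mirna not in name_idx:
                raise ValueError(f"planted survival effect references "
                                 f"unknown miRNA {eff.mirna!r}")
            z = np.log2(1e6 * weights_mat[name_idx[eff.mirna]] + 1.0)
            eta += eff.log_hr * (z - z.mean())
        latent = rng_sur.exponential(1.0, size=len(samples)) / (
            config.baseline_hazard * np.exp(eta))
        censor = rng_sur.uniform(0.0, config.follow_up_days,
                                 size=len(samples))
        time = np.minimum(latent, censor)
        event = (latent <= censor).astype(int)
        for smp, t, e in zip(samples, time, event):
            surv_rows.append((smp, endpoint, float(t), int(e)))

    survival = pd.DataFrame(
        surv_rows, columns=["sample", "endpoint", "time", "event"])
    tc = pd.DataFrame(true_counts, index=pd.Index(names, name="mirna"),
                      columns=samples)
    expr = pd.DataFrame(weights_mat, index=pd.Index(names, name="mirna"),
                        columns=samples)
    return Cohort(alignments, tc, clinical, survival, expr, annotation,
                  config)
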