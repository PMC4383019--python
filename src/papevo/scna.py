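"""Somatic copy-number pipeline.

Stages, in the order a multi-region analysis runs them:

1. :func:`normalize_logr` — quantile normalization of probe logR across
   regions plus MAD-based winsorization of outlier probes.
2. :func:`joint_segment` — exact dynamic-programming joint segmentation of
   all regions of a patient with shared breakpoints; the objective is the
   summed within-segment squared error plus a per-breakpoint penalty gamma.
3. :func:`fit_purity_ploidy` — grid search over purity alpha and ploidy tau
   (within +-0.5 of a prior from flow-cytometry DNA index); segment copy
   ratios are matched to the nearest integer copy-number lattice point,
   weighted by probe count, and the top-k models by log-likelihood returned.
4. :func:`harmonize_solutions` — pick one model per region, trading summed
   log-likelihood against pairwise disagreement in modal copy number across
   shared segments (multi-region samples of one tumour should agree).
5. :func:`call_arm_events` / :func:`summarize_cohort_scna` /
   :func:`cooccurrence_test` — arm-level gain/loss/cnLOH calls (>30% of the
   arm affected), cohort recurrence with involvement semantics, and an exact
   binomial co-occurrence test for the recurrent gains.
6. :func:`detect_focal_scna` — small (<1 Mb) events, filtered against
   germline CNVs by >50% overlap.
7. :func:`haplotype_concordance` — mirrored allelic imbalance: classify het
   probes major/minor in a reference region and test whether another region's
   major alleles are flipped (parallel evolution on the alternate haplotype).
8. :func:`dna_index` — flow-cytometry aneuploid/diploid G1 peak ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegmentProfile",
    "SegmentationParams",
    "PurityPloidySolution",
    "ArmEvent",
    "normalize_logr",
    "joint_segment",
    "fit_purity_ploidy",
    "harmonize_solutions",
    "call_arm_events",
    "summarize_cohort_scna",
    "cooccurrence_test",
    "detect_focal_scna",
    "haplotype_concordance",
    "dna_index",
    "read_cytoband_arms",
]


@dataclass
class SegmentationParams:
    """gamma: per-breakpoint cost of the joint segmentation objective;
    winsor_k: winsorization bound in MAD multiples."""

    gamma: float = 1000.0
    winsor_k: float = 2.5

    def __post_init__(self):
        if self.gamma <= 0 or self.winsor_k <= 0:
            raise ValueError("gamma and winsor_k must be > 0")


@dataclass
class SegmentProfile:
    """Piecewise-constant copy-number profile of one region.

    ``segments`` columns: chrom, start, end (0-based half-open), n_probes,
    logR, and once absolute copy number is assigned, q (integer) and loh
    (bool).  Segments are sorted and non-overlapping.
    """

    region: str
    segments: pd.DataFrame
    build: str = "synthetic"

    def validate(self) -> None:
        seg = self.segments
        for chrom, sub in seg.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if not (s.start.values == sub.start.values).all():
                raise ValueError("segments must be sorted by start within chromosome")
            if np.any(s.end.values[:-1] > s.start.values[1:]):
                raise ValueError("segments overlap")


@dataclass
class PurityPloidySolution:
    purity: float
    ploidy: float
    log_likelihood: float
    modal_cn: np.ndarray  # per-segment expected integer copy number

    def __post_init__(self):
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")


@dataclass
class ArmEvent:
    """One arm-level SCNA call.  ``arm`` is '7' for a whole chromosome,
    '17q' for a single arm; direction is gain | loss | cnLOH."""

    sample: str
    arm: str
    direction: str
    fraction: float = 1.0

    @property
    def chrom(self) -> str:
        return self.arm.rstrip("pq")

    @property
    def arms_involved(self) -> tuple:
        if self.arm.endswith(("p", "q")):
            return (self.arm,)
        return (self.arm + "p", self.arm + "q")


# ---------------------------------------------------------------------------
# normalization

def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def normalize_logr(
    matrix: pd.DataFrame,
    winsor_k: float = 2.5,
    window: int = 25,
) -> pd.DataFrame:
    """Quantile-normalize probe logR columns and winsorize outliers.

    Columns (regions) are mapped onto the mean empirical distribution (the
    average of the sorted columns); then, per column, probes further than
    ``winsor_k`` scaled MADs from a centred running median are clipped to that
    bound.  All-constant columns are left unchanged (with a warning attr).
    """
    if matrix.shape[1] < 1:
        raise ValueError("need at least one region column")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("logR values must be finite")
    out = values.copy()
    constant = np.array([np.ptp(values[:, j]) == 0 for j in range(values.shape[1])])
    if matrix.shape[1] > 1 and not constant.all():
        ref = np.mean(np.sort(values, axis=0), axis=1)
        for j in range(values.shape[1]):
            if constant[j]:
                continue
            order = np.argsort(values[:, j], kind="stable")
            ranked = np.empty_like(ref)
            ranked[order] = ref
            out[:, j] = ranked
    for j in range(out.shape[1]):
        if constant[j]:
            continue
        med = _running_median(out[:, j], window)
        resid = out[:, j] - med
        mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
        if mad == 0:
            continue
        out[:, j] = np.clip(out[:, j], med - winsor_k * mad, med + winsor_k * mad)
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    res.attrs["constant_columns"] = matrix.columns[constant].tolist()
    return res


# ---------------------------------------------------------------------------
# joint segmentation

def _segment_chromosome(y: np.ndarray, gamma: float) -> list:
    """Exact optimal partitioning of a (probes x regions) block.

    Minimizes sum_r sum_i (y - segment mean)^2 + gamma * n_breakpoints via
    O(n^2) dynamic programming with prefix sums.  Returns breakpoint indices
    (segment start positions, excluding 0).
    """
    n = y.shape[0]
    c1 = np.vstack([np.zeros(y.shape[1]), np.cumsum(y, axis=0)])
    c2 = np.vstack([np.zeros(y.shape[1]), np.cumsum(y**2, axis=0)])

    F = np.empty(n + 1)
    F[0] = -gamma
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        lengths = np.arange(j, 0, -1.0)  # j - i for i = 0..j-1
        sse = (c2[j] - c2[:j]) - (c1[j] - c1[:j]) ** 2 / lengths[:, None]
        total = F[:j] + gamma + sse.sum(axis=1)
        i = int(np.argmin(total))
        F[j] = total[i]
        back[j] = i
    # trace back
    cuts = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            cuts.append(i)
        j = i
    return sorted(cuts)


def joint_segment(
    matrix: pd.DataFrame,
    probe_info: pd.DataFrame,
    params: SegmentationParams | None = None,
) -> dict:
    """Jointly segment all regions of one patient with shared breakpoints.

    ``matrix`` is probes x regions (normalized logR); ``probe_info`` carries
    chrom and pos per probe, sorted by (chrom, pos).  Returns a dict region ->
    :class:`SegmentProfile`; breakpoints are common to all regions, segment
    means are region-specific.
    """
    params = params or SegmentationParams()
    if list(matrix.index) != list(probe_info.index):
        raise ValueError("matrix and probe_info must share the same probe index")
    pos = probe_info["pos"].to_numpy()
    for chrom, sub in probe_info.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) >= 0):
            raise ValueError(f"probes on {chrom} are not sorted by position")

    profiles = {region: [] for region in matrix.columns}
    for chrom, sub in probe_info.groupby("chrom", sort=False):
        idx = probe_info.index.get_indexer(sub.index)
        y = matrix.to_numpy(dtype=float)[idx]
        cuts = _segment_chromosome(y, params.gamma)
        bounds = [0] + cuts + [len(idx)]
        p = pos[idx]
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = int(p[a])
            end = int(p[b - 1]) + 1
            for j, region in enumerate(matrix.columns):
                profiles[region].append(
                    (chrom, start, end, b - a, float(y[a:b, j].mean()))
                )
    return {
        region: SegmentProfile(
            region=str(region),
            segments=pd.DataFrame(
                rows, columns=["chrom", "start", "end", "n_probes", "logR"]
            ),
        )
        for region, rows in profiles.items()
    }


# ---------------------------------------------------------------------------
# purity / ploidy

def fit_purity_ploidy(
    profile: SegmentProfile,
    prior_ploidy: float = 2.0,
    top_k: int = 5,
    sigma: float = 0.05,
    q_max: int = 8,
    purity_grid: tuple = (0.05, 1.0, 0.01),
    ploidy_step: float = 0.05,
    diploid_penalty: float = 0.01,
) -> list:
    """Grid-search purity/ploidy fit of a relative copy-ratio profile.

    For candidate (alpha, tau) the expected relative ratio of integer copy
    number q is ``(alpha*q + 2*(1-alpha)) / (alpha*tau + 2*(1-alpha))``; each
    segment's observed ratio ``2**logR`` is assigned the nearest lattice q in
    [0, q_max] and scored under a Gaussian on logR with sd ``sigma`` per
    probe, weighted by probe count.  Ploidy is searched within +-0.5 of
    ``prior_ploidy`` (e.g. from a flow-cytometry DNA index).

    Relative copy ratios carry an intrinsic degeneracy: the model
    (alpha/2, 2*tau - 2) with copy numbers 2q - 2 reproduces any profile
    exactly.  A karyotype-parsimony prior of ``diploid_penalty`` log-units
    per probe per copy of distance from the diploid state breaks these exact
    ties toward the least-aberrant karyotype (the alternate models remain
    visible in the returned top-k ranking); it is far smaller than any
    genuine likelihood gap.  Returns the ``top_k`` solutions sorted by
    decreasing penalized log-likelihood.
    """
    seg = profile.segments
    if len(seg) == 0:
        raise ValueError("empty segment profile")
    logr = seg["logR"].to_numpy(dtype=float)
    w = seg["n_probes"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("no probe coverage in profile")

    alphas = np.arange(purity_grid[0], purity_grid[1] + 1e-9, purity_grid[2])
    taus = np.arange(prior_ploidy - 0.5, prior_ploidy + 0.5 + 1e-9, ploidy_step)
    qs = np.arange(0, q_max + 1)

    solutions = []
    const = -0.5 * np.log(2 * np.pi * sigma**2)
    for alpha in alphas:
        for tau in taus:
            denom = alpha * tau + 2 * (1 - alpha)
            ratios = (alpha * qs + 2 * (1 - alpha)) / denom
            with np.errstate(divide="ignore"):
                lattice = np.log2(np.maximum(ratios, 1e-12))
            d = np.abs(logr[:, None] - lattice[None, :])
            qhat = qs[np.argmin(d, axis=1)]
            resid = logr - lattice[qhat]
            ll = float(np.sum(w * (const - resid**2 / (2 * sigma**2))))
            ll -= diploid_penalty * float(np.sum(w * np.abs(qhat - 2)))
            solutions.append(
                PurityPloidySolution(
                    purity=round(float(alpha), 4),
                    ploidy=round(float(tau), 4),
                    log_likelihood=ll,
                    modal_cn=qhat.astype(int),
                )
            )
    solutions.sort(key=lambda s: -s.log_likelihood)
    return solutions[:top_k]


def harmonize_solutions(
    per_region: dict,
    lam: float | None = None,
    mode: str = "weighted",
) -> dict:
    """Choose one purity/ploidy model per region of a tumour.

    ``per_region`` maps region id -> list of :class:`PurityPloidySolution`
    over a shared segment scaffold.  The objective over each combination in
    the product of candidate lists is ``sum(log-likelihood) - lam * sum over
    region pairs of mean |modal CN difference|``; lam defaults to twice the
    mean per-segment log-likelihood magnitude of the best models, making the
    distance term comparable to one segment's likelihood.  ``mode='lexico'``
    minimizes total CN distance first and breaks ties by likelihood.  Returns
    {"choice": {region: solution}, "ranking": DataFrame}.
    """
    regions = sorted(per_region)
    if not regions:
        raise ValueError("no regions supplied")
    n_seg = {len(s.modal_cn) for sols in per_region.values() for s in sols}
    if len(n_seg) != 1:
        raise ValueError("solutions must share one segment scaffold")
    n_seg = n_seg.pop()
    if n_seg == 0:
        raise ValueError("no shared segments")
    if len(regions) == 1:
        best = max(per_region[regions[0]], key=lambda s: s.log_likelihood)
        return {"choice": {regions[0]: best}, "ranking": None}

    if lam is None:
        scale = np.mean(
            [abs(max(sols, key=lambda s: s.log_likelihood).log_likelihood) / n_seg
             for sols in per_region.values()]
        )
        lam = 2.0 * scale

    records = []
    best_combo, best_score = None, None
    for combo in itertools.product(*(per_region[r] for r in regions)):
        ll = sum(s.log_likelihood for s in combo)
        dist = 0.0
        for a, b in itertools.combinations(range(len(combo)), 2):
            dist += float(np.mean(np.abs(combo[a].modal_cn - combo[b].modal_cn)))
        score = (-dist, ll) if mode == "lexico" else ll - lam * dist
        records.append((combo, ll, dist, score))
        if best_score is None or score > best_score:
            best_score, best_combo = score, combo
    ranking = pd.DataFrame(
        [
            {
                "models": tuple((s.purity, s.ploidy) for s in combo),
                "log_likelihood": ll,
                "cn_distance": dist,
            }
            for combo, ll, dist, _ in sorted(records, key=lambda r: r[3], reverse=True)
        ]
    )
    return {"choice": dict(zip(regions, best_combo)), "ranking": ranking}


# ---------------------------------------------------------------------------
# arm events

def read_cytoband_arms(path) -> pd.DataFrame:
    """Collapse a UCSC cytoBand file into arm spans (chrom, arm, start, end)."""
    bands = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
    )
    bands["arm"] = bands["band"].str[0]
    bands = bands[bands["arm"].isin(["p", "q"])]
    g = bands.groupby(["chrom", "arm"], sort=False).agg(
        start=("start", "min"), end=("end", "max")
    )
    return g.reset_index()


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def call_arm_events(
    profile: SegmentProfile,
    arm_table: pd.DataFrame,
    threshold: float = 0.30,
    sample: str | None = None,
) -> list:
    """Call arm-level gains/losses/cnLOH from an absolute CN profile.

    The affected fraction of an arm is the summed overlap of segments with
    q > 2 (gain), q < 2 (loss) or q == 2 with an LOH flag (cnLOH), divided by
    the arm length; an event is called when the fraction exceeds
    ``threshold``.  Arms with zero probe coverage (e.g. acrocentric p-arms)
    are skipped as uncallable.  When both arms of a chromosome carry the same
    direction, one whole-chromosome event is reported instead (label '7'
    rather than '7p' + '7q').
    """
    seg = profile.segments
    if "q" not in seg.columns:
        raise ValueError("absolute copy number (column 'q') must be assigned first")
    sample = sample or profile.region
    loh = seg["loh"] if "loh" in seg.columns else pd.Series(False, index=seg.index)

    per_arm = {}
    for _, arm in arm_table.iterrows():
        arm_len = arm.end - arm.start
        sub = seg[seg.chrom == arm.chrom]
        covered = sum(
            _overlap(s.start, s.end, arm.start, arm.end) for s in sub.itertuples()
        )
        if covered == 0:
            continue  # uncallable arm
        acc = {"gain": 0, "loss": 0, "cnLOH": 0}
        for s, is_loh in zip(sub.itertuples(), loh[sub.index]):
            ov = _overlap(s.start, s.end, arm.start, arm.end)
            if ov == 0:
                continue
            if s.q > 2:
                acc["gain"] += ov
            elif s.q < 2:
                acc["loss"] += ov
            elif is_loh:
                acc["cnLOH"] += ov
        for direction, length in acc.items():
            frac = length / arm_len
            if frac > threshold:
                per_arm[(arm.chrom, arm.arm, direction)] = frac

    events = []
    chroms = {c for c, _, _ in per_arm}
    for chrom in sorted(chroms):
        label = str(chrom).removeprefix("chr")
        for direction in ("gain", "loss", "cnLOH"):
            has_p = (chrom, "p", direction) in per_arm
            has_q = (chrom, "q", direction) in per_arm
            if has_p and has_q:
                frac = (per_arm[(chrom, "p", direction)] + per_arm[(chrom, "q", direction)]) / 2
                events.append(ArmEvent(sample, label, direction, frac))
            elif has_p:
                events.append(ArmEvent(sample, label + "p", direction,
                                       per_arm[(chrom, "p", direction)]))
            elif has_q:
                events.append(ArmEvent(sample, label + "q", direction,
                                       per_arm[(chrom, "q", direction)]))
    return events


def _involves(event: ArmEvent, query: str) -> bool:
    """Does an event's span involve a query arm or chromosome?

    Query '7' (chromosome) is involved by any event on chr7; query '17q' by a
    whole-chromosome event '17' or by '17q' itself.
    """
    if query.endswith(("p", "q")):
        return query in event.arms_involved
    return event.chrom == query


def summarize_cohort_scna(events_by_sample: dict) -> dict:
    """Cohort-level arm SCNA accounting.

    ``events_by_sample`` maps sample id -> list of :class:`ArmEvent` (samples
    flagged complex should be excluded upstream).  Recurrence counts, for
    each queried arm/chromosome and direction, the number of samples with at
    least one event involving it; totals count each listed event once.
    """
    counts = {s: len(evts) for s, evts in events_by_sample.items()}
    all_events = [e for evts in events_by_sample.values() for e in evts]
    n_gain = sum(1 for e in all_events if e.direction == "gain")
    n_loss = sum(1 for e in all_events if e.direction == "loss")

    queries = set()
    for e in all_events:
        queries.add(e.arm)
        queries.update(e.arms_involved)
        queries.add(e.chrom)
    recurrence = {}
    for q in sorted(queries):
        for direction in ("gain", "loss", "cnLOH"):
            n = sum(
                1
                for s, evts in events_by_sample.items()
                if any(_involves(e, q) and e.direction == direction for e in evts)
            )
            if n:
                recurrence[f"{q}:{direction}"] = n

    per_sample = np.array(list(counts.values())) if counts else np.array([0])
    return {
        "n_samples": len(events_by_sample),
        "total_events": len(all_events),
        "per_sample_counts": counts,
        "median_per_sample": float(np.median(per_sample)) if counts else 0.0,
        "min_per_sample": int(per_sample.min()) if counts else 0,
        "max_per_sample": int(per_sample.max()) if counts else 0,
        "n_gain": n_gain,
        "n_loss": n_loss,
        "gain_loss_ratio": (n_gain / n_loss) if n_loss else None,
        "recurrence": recurrence,
    }


def cooccurrence_test(
    events_by_sample: dict,
    target_arms: set,
    n_samples: int | None = None,
    seed: int = 0,
) -> dict:
    """Exact binomial test for co-occurrence of recurrent gains.

    Construction: each sample either carries >= 2 of the target gains or not.
    Under independence, the per-sample probability of >= 2 target gains is
    computed from the marginal gain frequencies (Poisson-binomial, exact by
    expansion); the one-sided p is P(X >= observed) for X ~ Binomial(n, p0).
    """
    if not target_arms or len(target_arms) < 2:
        raise ValueError("need >= 2 target arms")
    n = n_samples or len(events_by_sample)
    marg = {}
    for a in target_arms:
        marg[a] = sum(
            1 for evts in events_by_sample.values()
            if any(_involves(e, a) and e.direction == "gain" for e in evts)
        ) / n
    observed = sum(
        1
        for evts in events_by_sample.values()
        if sum(
            any(_involves(e, a) and e.direction == "gain" for e in evts)
            for a in target_arms
        ) >= 2
    )
    # P(>= 2 of independent Bernoullis)
    fs = list(marg.values())
    p_none = float(np.prod([1 - f for f in fs]))
    p_one = float(
        sum(f * np.prod([1 - g for j, g in enumerate(fs) if j != i])
            for i, f in enumerate(fs))
    )
    p0 = max(min(1 - p_none - p_one, 1.0), 0.0)
    if observed == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(observed, n, p0, alternative="greater").pvalue)
    return {"observed": observed, "expected_prob": p0, "n": n,
            "marginals": marg, "p": p}


def detect_focal_scna(
    profile: SegmentProfile,
    germline_cnvs: list | None = None,
    max_size: int = 1_000_000,
) -> pd.DataFrame:
    """Small (< ``max_size`` bp) non-diploid segments, germline-CNV filtered.

    A focal segment is dropped when a single germline CNV interval (chrom,
    start, end) covers more than 50% of it.
    """
    seg = profile.segments
    if "q" not in seg.columns:
        raise ValueError("absolute copy number (column 'q') must be assigned first")
    germline_cnvs = germline_cnvs or []
    rows = []
    for s in seg.itertuples():
        size = s.end - s.start
        if size >= max_size or s.q == 2:
            continue
        cov = max(
            (_overlap(s.start, s.end, c[1], c[2]) for c in germline_cnvs
             if str(c[0]) == str(s.chrom)),
            default=0,
        )
        if cov / size > 0.5:
            continue
        rows.append(
            (s.chrom, s.start, s.end, size, int(s.q),
             "gain" if s.q > 2 else "loss")
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "size", "q", "direction"]
    )


def haplotype_concordance(
    probes: pd.DataFrame,
    chrom: str,
    span: tuple,
    regions: list,
    reference_region: str,
    min_het_probes: int = 20,
    alpha_level: float = 0.05,
) -> dict:
    """Mirrored-allelic-imbalance test for a shared SCNA.

    Het probes inside ``span`` on ``chrom`` are classed major (BAF > 0.5) or
    minor (BAF < 0.5) in the reference region (the highest-cellularity region
    carrying the event).  For every other region the fraction of probes whose
    major allele flips is tested against 0.5 with a two-sided exact binomial
    test: 'inverted' (flip fraction > 0.5, p < alpha_level) indicates the
    alternate haplotype was affected — parallel evolution; 'concordant' is the
    mirror case; anything else is 'indeterminate'.
    """
    start, end = span
    het = probes[
        (probes.chrom == chrom)
        & (probes.pos >= start)
        & (probes.pos < end)
        & probes.is_het_germline
    ]
    ref = het[het.region == reference_region].set_index("probe_id")
    results = {}
    for region in regions:
        if region == reference_region:
            continue
        other = het[het.region == region].set_index("probe_id")
        common = ref.index.intersection(other.index)
        ref_major = ref.loc[common, "BAF"] > 0.5
        oth_major = other.loc[common, "BAF"] > 0.5
        informative = (ref.loc[common, "BAF"] != 0.5) & (other.loc[common, "BAF"] != 0.5)
        n = int(informative.sum())
        if n < min_het_probes:
            results[region] = {"call": "indeterminate", "n_het": n,
                               "flip_fraction": None, "p": None}
            continue
        flips = int((ref_major[informative] != oth_major[informative]).sum())
        frac = flips / n
        p = float(stats.binomtest(flips, n, 0.5).pvalue)
        if frac > 0.5 and p < alpha_level:
            call = "inverted"
        elif frac < 0.5 and p < alpha_level:
            call = "concordant"
        else:
            call = "indeterminate"
        results[region] = {"call": call, "n_het": n, "flip_fraction": frac, "p": p}
    return results


def dna_index(aneuploid_g1: float, diploid_g1: float) -> float:
    """Flow-cytometry DNA index: aneuploid G1 peak over diploid G1 peak
    (1.0 = diploid)."""
    if aneuploid_g1 <= 0 or diploid_g1 <= 0:
        raise ValueError("G1 peak channel values must be > 0")
    return aneuploid_g1 / diploid_g1


def assign_absolute_cn(
    profile: SegmentProfile, solution: PurityPloidySolution
) -> SegmentProfile:
    """Attach a solution's modal integer copy numbers to the segment table."""
    seg = profile.segments.copy()
    seg["q"] = solution.modal_cn
    return SegmentProfile(region=profile.region, segments=seg, build=profile.build)
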