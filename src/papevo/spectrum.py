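"""Substitution spectra, Ts:Tv / dN:dS summaries and spectrum deviation tests.

Single-base substitutions are folded onto the pyrimidine strand into the six
canonical classes (C:G>T:A, C:G>A:T, C:G>G:C, T:A>C:G, T:A>A:T, T:A>G:C).
Each sample's spectrum is tested for deviation from the cohort's global
spectrum with a Monte-Carlo multinomial goodness-of-fit test; false-discovery
control uses weighted Benjamini-Hochberg with weights proportional to sample
mutation count (plain BH available by flag).  Trunk vs branch spectra of a
multi-region tumour are compared with a 6x2 contingency test, switching to a
simulated null when expected counts are small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASSES",
    "SpectrumProfile",
    "substitution_class",
    "spectrum_profile",
    "spectrum_deviation_test",
    "compare_trunk_branch_spectra",
]

CLASSES = ("C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>A:T", "T:A>G:C")
TRANSITIONS = ("C:G>T:A", "T:A>C:G")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_CLASS_MAP = {}
for _ref, _alt in [(r, a) for r in "CT" for a in "ACGT" if a != r]:
    _pair = f"{_ref}:{_COMPLEMENT[_ref]}>{_alt}:{_COMPLEMENT[_alt]}"
    _CLASS_MAP[(_ref, _alt)] = _pair
    _CLASS_MAP[(_COMPLEMENT[_ref], _COMPLEMENT[_alt])] = _pair


def substitution_class(ref: str, alt: str) -> str:
    """Fold a single-base substitution onto the pyrimidine strand.

    (C,T) and (G,A) both map to C:G>T:A, etc.
    """
    key = (ref.upper(), alt.upper())
    if key not in _CLASS_MAP:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    return _CLASS_MAP[key]


@dataclass
class SpectrumProfile:
    """Six-class substitution counts plus Ts:Tv and dN/dS count ratios.

    Ratios are None (flagged undefined) when their denominator is zero.
    """

    sample: str
    counts: dict
    n_nonsynonymous: int = 0
    n_synonymous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ts_tv(self) -> float | None:
        ts = sum(self.counts[c] for c in TRANSITIONS)
        tv = self.total - ts
        return ts / tv if tv else None

    @property
    def dn_ds(self) -> float | None:
        return self.n_nonsynonymous / self.n_synonymous if self.n_synonymous else None

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CLASSES], dtype=float)


def spectrum_profile(variants, sample: str = "sample") -> SpectrumProfile:
    """Build a spectrum profile from SNVs.

    ``variants`` may be SomaticVariant objects or any records with ref/alt
    (and optionally effect) attributes; non-SNVs are skipped.
    """
    counts = {c: 0 for c in CLASSES}
    n_ns = n_s = 0
    for v in variants:
        ref, alt = v.ref.upper(), v.alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            continue
        counts[substitution_class(ref, alt)] += 1
        effect = (getattr(v, "effect", None) or "").lower()
        if effect.startswith("non-synonymous") or effect in ("stopgain", "stopgain snv"):
            n_ns += 1
        elif effect == "synonymous":
            n_s += 1
    return SpectrumProfile(sample=sample, counts=counts,
                           n_nonsynonymous=n_ns, n_synonymous=n_s)


def _gof_stat(obs: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Pearson chi-square; infinite when a zero-expectation class is hit."""
    obs = np.atleast_2d(obs)
    expected = np.atleast_2d(expected)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - expected) ** 2 / expected
    bad = ((expected == 0) & (obs > 0)).any(axis=1)
    stat = np.where(expected > 0, terms, 0.0).sum(axis=1)
    return np.where(bad, np.inf, stat)


def _mc_gof_p(obs: np.ndarray, ref_counts: np.ndarray, n_sim: int, rng) -> float:
    """Monte-Carlo goodness-of-fit p-value of ``obs`` against a reference
    spectrum that is itself estimated from ``ref_counts``.

    The null resamples BOTH sides (parametric bootstrap): reference counts
    are redrawn at their own total so the p-value stays calibrated even
    though the reference proportions are estimates, not truth.
    """
    n = int(obs.sum())
    n_ref = int(ref_counts.sum())
    if n == 0 or n_ref == 0:
        return 1.0
    probs = ref_counts / n_ref
    obs_stat = _gof_stat(obs, n * probs)[0]
    sims = rng.multinomial(n, probs, size=n_sim).astype(float)
    sims_ref = rng.multinomial(n_ref, probs, size=n_sim).astype(float)
    stats_sim = _gof_stat(sims, n * sims_ref / n_ref)
    return float((1 + np.sum(stats_sim >= obs_stat)) / (n_sim + 1))


def weighted_bh(pvals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Benjamini-Hochberg adjusted p-values.

    Weights are normalized to mean 1; each p is divided by its weight before
    the standard step-up adjustment (Genovese-Roeder weighted FDR).
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.mean()
    p = np.asarray(pvals, dtype=float) / np.where(w > 0, w, np.inf)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, p[i] * m / (rank + 1))
        adj[i] = min(running_min, 1.0)
    return adj


def spectrum_deviation_test(
    profiles: list,
    n_sim: int = 10_000,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Test each sample's spectrum against the pooled spectrum of the others.

    For each sample a Monte-Carlo multinomial goodness-of-fit p-value is
    computed against the leave-one-out pooled class proportions (>= ``n_sim``
    draws, seeded).  The q column is weighted BH-adjusted with weights
    proportional to sample mutation count (mean-normalized); set
    ``weighted=False`` for plain BH.  Samples with zero SNVs get p = 1 and an
    ``undefined`` flag.
    """
    if len(profiles) < 2:
        raise ValueError("spectrum deviation test needs >= 2 samples")
    mat = np.vstack([p.as_array() for p in profiles])
    totals = mat.sum(axis=1)
    pooled = mat.sum(axis=0)
    ss = np.random.SeedSequence(seed)
    pvals, flags = [], []
    for i, child in enumerate(ss.spawn(len(profiles))):
        rng = np.random.Generator(np.random.PCG64(child))
        if totals[i] == 0:
            pvals.append(1.0)
            flags.append("no_snvs")
            continue
        ref = pooled - mat[i]
        if ref.sum() == 0:
            pvals.append(1.0)
            flags.append("empty_reference")
            continue
        pvals.append(_mc_gof_p(mat[i], ref, n_sim, rng))
        flags.append("")
    pvals = np.array(pvals)
    weights = totals if weighted else np.ones_like(totals)
    if np.all(weights == 0):
        weights = np.ones_like(totals)
    weights = np.where(weights == 0, weights[weights > 0].min() if np.any(weights > 0) else 1.0,
                       weights)
    q = weighted_bh(pvals, weights)
    return pd.DataFrame(
        {
            "sample": [p.sample for p in profiles],
            "n_snvs": totals.astype(int),
            "p": pvals,
            "q_weighted" if weighted else "q": q,
            "flag": flags,
        }
    )


def compare_trunk_branch_spectra(
    presence_matrix: pd.DataFrame,
    variants,
    n_sim: int = 10_000,
    seed: int = 0,
) -> dict:
    """Compare trunk vs branch substitution spectra within one tumour.

    Trunk mutations are those present in every evaluable region of the
    presence matrix (mutation x region); the rest are branch.  Returns a dict
    with the 6x2 table, p-value and a flag; the test is a chi-square on the
    contingency table, replaced by a seeded Monte-Carlo null (conditional
    multinomial draws from the pooled spectrum) when any expected count is
    below 5.  Degenerate inputs (empty trunk or branch) give p = None.
    """
    by_id = {}
    for v in variants:
        vid = getattr(v, "mutation_id", None) or f"{v.chrom}:{v.pos}"
        by_id[vid] = v
    trunk_counts = np.zeros(len(CLASSES))
    branch_counts = np.zeros(len(CLASSES))
    if presence_matrix.shape[1] < 2:
        return {"p": None, "flag": "single_region", "table": None}
    for mut_id, row in presence_matrix.iterrows():
        v = by_id.get(mut_id)
        if v is None:
            continue
        ref, alt = v.ref.upper(), v.alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            continue
        cls = CLASSES.index(substitution_class(ref, alt))
        evaluable = row.dropna()
        if len(evaluable) and evaluable.all():
            trunk_counts[cls] += 1
        else:
            branch_counts[cls] += 1
    n_t, n_b = trunk_counts.sum(), branch_counts.sum()
    table = pd.DataFrame({"trunk": trunk_counts, "branch": branch_counts}, index=list(CLASSES))
    if n_t == 0 or n_b == 0:
        return {"p": None, "flag": "empty_trunk_or_branch", "table": table}
    pooled = (trunk_counts + branch_counts) / (n_t + n_b)
    keep = (trunk_counts + branch_counts) > 0
    expected = np.outer(pooled, [n_t, n_b])

    def chi2_stat(t, b):
        e = np.outer((t + b) / (n_t + n_b), [n_t, n_b])
        with np.errstate(divide="ignore", invalid="ignore"):
            x = (np.stack([t, b], axis=1) - e) ** 2 / e
        return float(np.nansum(x[keep]))

    if np.all(expected[keep] >= 5):
        _, p, _, _ = stats.chi2_contingency(table.values[keep])
        flag = "chi2"
    else:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        obs = chi2_stat(trunk_counts, branch_counts)
        sims_t = rng.multinomial(int(n_t), pooled, size=n_sim).astype(float)
        sims_b = rng.multinomial(int(n_b), pooled, size=n_sim).astype(float)
        sim_stats = np.array([chi2_stat(sims_t[s], sims_b[s]) for s in range(n_sim)])
        p = float((1 + np.sum(sim_stats >= obs)) / (n_sim + 1))
        flag = "monte_carlo"
    return {"p": float(p), "flag": flag, "table": table}
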