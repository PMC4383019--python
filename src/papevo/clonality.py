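"""Cancer-cell fractions and Dirichlet-process binomial clustering of mutations.

The cancer cell fraction (CCF) of a mutation with ``alt``/``depth`` reads,
local total copy number ``q``, multiplicity ``m`` and tumour purity ``alpha``
is ``CCF = VAF * (alpha*q + 2*(1-alpha)) / (alpha*m)`` — the fraction of
tumour cells carrying the mutation.  Mutations (and, optionally, arm-level
copy-number events encoded as pseudo-variants) are clustered across regions
with a Chinese-restaurant-process Gibbs sampler:

* cluster parameter: a per-region CCF vector phi in [0,1]^R with a uniform
  base measure;
* emission: alt ~ Binomial(depth, xi) with xi = alpha*m*phi_r /
  (alpha*q + 2*(1-alpha)) — a linear map of phi, so the prior predictive for
  a new cluster has a closed form via the incomplete beta function;
* the DP concentration parameter is resampled under a gamma(a, b) prior
  (Escobar & West auxiliary-variable scheme);
* the reported clustering is a consensus: average-linkage cut at 0.5 of the
  posterior co-assignment (similarity) matrix, which makes membership
  invariant to label switching and to mutation input order.

The number of consensus clusters is the predicted clone count; the cluster
with the highest mean CCF across regions is the major clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CcfObservation",
    "CloneClusterSet",
    "McmcSettings",
    "compute_ccf",
    "encode_scna_pseudovariant",
    "dp_cluster",
    "classify_clonality",
]

CCF_CLIP = 1.2  # diagnostic overshoot retained up to here, clipped for clustering


@dataclass
class CcfObservation:
    """One (mutation, region) read-count observation with its CCF estimate."""

    mutation_id: str
    region: str
    depth: int
    alt_count: int
    q: int
    m: int
    purity: float
    ccf: float
    ccf_low: float
    ccf_high: float
    flag: str = ""


@dataclass
class McmcSettings:
    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class CloneClusterSet:
    """Consensus clusters of mutations with per-region mean CCFs."""

    clusters: dict  # cluster id -> {"ccf": {region: mean}, "members": [...]}
    similarity: pd.DataFrame
    alpha_dp_mean: float
    settings: McmcSettings
    labels: dict = field(default_factory=dict)  # cluster id -> major | sub-clonal

    @property
    def n_clones(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict:
        out = {}
        for cid, info in self.clusters.items():
            for m in info["members"]:
                out[m] = cid
        return out


def compute_ccf(
    depth: int,
    alt_count: int,
    purity: float,
    q: int = 2,
    m: int = 1,
    mutation_id: str = "mut",
    region: str = "R1",
    ci: float = 0.95,
) -> CcfObservation:
    """CCF point estimate with a Clopper-Pearson interval propagated from VAF."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    if q < 0 or m < 1:
        raise ValueError("need q >= 0 and m >= 1")
    flag = ""
    if q == 0 and alt_count > 0:
        flag = "inconsistent_cn"
    vaf = alt_count / depth
    scale = (purity * q + 2 * (1 - purity)) / (purity * max(m, 1))
    lo_q = (1 - ci) / 2
    vaf_lo = stats.beta.ppf(lo_q, alt_count, depth - alt_count + 1) if alt_count > 0 else 0.0
    vaf_hi = (
        stats.beta.ppf(1 - lo_q, alt_count + 1, depth - alt_count)
        if alt_count < depth else 1.0
    )
    return CcfObservation(
        mutation_id=mutation_id,
        region=region,
        depth=int(depth),
        alt_count=int(alt_count),
        q=int(q),
        m=int(m),
        purity=float(purity),
        ccf=float(min(vaf * scale, CCF_CLIP)),
        ccf_low=float(vaf_lo * scale),
        ccf_high=float(vaf_hi * scale),
        flag=flag,
    )


def encode_scna_pseudovariant(
    probes: pd.DataFrame,
    chrom: str,
    span: tuple,
    region: str,
    purity: float,
    direction: int = 1,
    per_probe_precision: int = 40,
    event_id: str | None = None,
) -> CcfObservation:
    """Encode an arm-level SCNA as a dummy read-count observation.

    The event's aberrant-cell fraction is estimated from the mean major-allele
    BAF of het probes in the span: for a single-copy gain carried by a
    fraction rho of all cells the major-allele frequency is (1+rho)/(2+rho);
    for a loss it is 1/(2-rho).  The CCF is rho/purity, and the dummy
    (depth, alt) pair implies the same VAF an SNV with q=2, m=1 and that CCF
    would have, at an effective depth of het-probe count x
    ``per_probe_precision`` — so the pseudo-variant drops straight into
    :func:`dp_cluster` beside real SNVs.
    """
    start, end = span
    het = probes[
        (probes.chrom == chrom)
        & (probes.pos >= start)
        & (probes.pos < end)
        & probes.is_het_germline
        & (probes.region == region)
    ]
    if len(het) == 0:
        raise ValueError(f"no heterozygous probes in {chrom}:{start}-{end} ({region})")
    major = np.maximum(het["BAF"].to_numpy(), 1 - het["BAF"].to_numpy())
    m_bar = float(np.clip(major.mean(), 0.5, 0.999))
    if direction >= 0:
        rho = (2 * m_bar - 1) / (1 - m_bar)
    else:
        rho = 2 - 1 / m_bar
    rho = float(np.clip(rho, 0.0, 1.0))
    phi = float(np.clip(rho / purity, 0.0, 1.0))
    depth = int(len(het) * per_probe_precision)
    xi = purity * phi / 2.0  # q=2, m=1 convention
    alt = int(round(depth * xi))
    return CcfObservation(
        mutation_id=event_id or f"scna_{chrom}_{start}",
        region=region,
        depth=depth,
        alt_count=alt,
        q=2,
        m=1,
        purity=float(purity),
        ccf=phi,
        ccf_low=phi,
        ccf_high=phi,
        flag="scna_pseudovariant",
    )


# ---------------------------------------------------------------------------
# Dirichlet-process sampler internals

def _log_predictive(k: float, n: float, a: float) -> float:
    """log Integral_0^1 (a*phi)^k (1-a*phi)^(n-k) dphi  (binomial coefficient
    omitted, matching the cluster-likelihood terms)."""
    if n == 0:
        return 0.0
    # substitute u = a*phi: (1/a) * B(k+1, n-k+1) * I_a(k+1, n-k+1)
    log_b = special.betaln(k + 1, n - k + 1)
    inc = special.betainc(k + 1, n - k + 1, a)
    if inc <= 0:
        return -np.inf
    return float(-np.log(a) + log_b + np.log(inc))


def _sample_alpha_dp(alpha: float, n: int, k: int, prior: tuple, rng) -> float:
    """Escobar & West (1995) resampling of the DP concentration parameter."""
    a, b = prior
    eta = rng.beta(alpha + 1, n)
    odds = (a + k - 1) / (n * (b - np.log(eta)))
    if rng.random() < odds / (1 + odds):
        return float(rng.gamma(a + k, 1 / (b - np.log(eta))))
    return float(rng.gamma(a + k - 1, 1 / (b - np.log(eta))))


def dp_cluster(
    observations: list,
    mcmc: McmcSettings | None = None,
    alpha_prior: tuple = (1.0, 1.0),
    phi_grid_size: int = 101,
) -> CloneClusterSet:
    """Cluster mutations into clones by their per-region CCFs.

    ``observations`` is a flat list of :class:`CcfObservation`; a mutation may
    be observed in any subset of regions (missing regions are missing data,
    not zeros).  See the module docstring for the model.  Deterministic for a
    fixed :class:`McmcSettings` seed.
    """
    mcmc = mcmc or McmcSettings()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(mcmc.seed)))

    mut_ids = sorted({o.mutation_id for o in observations})
    regions = sorted({o.region for o in observations})
    n_mut, n_reg = len(mut_ids), len(regions)
    if n_mut == 0:
        raise ValueError("no observations")
    mi = {m: i for i, m in enumerate(mut_ids)}
    ri = {r: j for j, r in enumerate(regions)}

    k = np.zeros((n_mut, n_reg))
    n = np.zeros((n_mut, n_reg))
    a = np.zeros((n_mut, n_reg))  # xi = a * phi
    seen = np.zeros((n_mut, n_reg), dtype=bool)
    for o in observations:
        i, j = mi[o.mutation_id], ri[o.region]
        k[i, j] = o.alt_count
        n[i, j] = o.depth
        a[i, j] = o.purity * o.m / (o.purity * o.q + 2 * (1 - o.purity))
        seen[i, j] = True
    a = np.clip(a, 1e-9, 1.0)

    # per-mutation new-cluster predictive (constant across sweeps)
    log_pred = np.zeros(n_mut)
    for i in range(n_mut):
        log_pred[i] = sum(
            _log_predictive(k[i, j], n[i, j], a[i, j]) for j in range(n_reg) if seen[i, j]
        )

    grid = np.linspace(0.0, 1.0, phi_grid_size)

    def obs_loglik(i: int, phi: np.ndarray) -> np.ndarray:
        """log-likelihood of mutation i under cluster CCF rows phi (C x R)."""
        xi = a[i] * phi
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = k[i] * np.log(xi) + (n[i] - k[i]) * np.log1p(-xi)
        ll = np.where(seen[i], np.nan_to_num(ll, nan=0.0, neginf=-1e30), 0.0)
        return ll.sum(axis=1)

    def sample_phi(members: list) -> np.ndarray:
        """Griddy-Gibbs draw of a cluster's per-region CCF vector."""
        phi = np.empty(n_reg)
        for j in range(n_reg):
            obs_i = [i for i in members if seen[i, j]]
            if not obs_i:
                phi[j] = rng.random()
                continue
            kk = k[obs_i, j][:, None]
            nn = n[obs_i, j][:, None]
            aa = a[obs_i, j][:, None]
            xi = aa * grid[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                lp = kk * np.log(xi) + (nn - kk) * np.log1p(-np.minimum(xi, 1 - 1e-12))
            lp = np.where((kk == 0) & (grid[None, :] == 0), 0.0, lp)
            lp = np.nan_to_num(lp, nan=-1e30, neginf=-1e30).sum(axis=0)
            w = np.exp(lp - lp.max())
            w /= w.sum()
            phi[j] = grid[rng.choice(phi_grid_size, p=w)]
        return phi

    # initialize: quantize mean CCF to 0.1 bins
    mean_ccf = np.where(seen, np.divide(k, np.maximum(n, 1)) / a, np.nan)
    init_key = np.round(np.nanmean(np.clip(mean_ccf, 0, 1), axis=1) * 10)
    uniq = {key: c for c, key in enumerate(sorted(set(init_key)))}
    assign = np.array([uniq[key] for key in init_key])
    clusters = {c: [i for i in range(n_mut) if assign[i] == c] for c in set(assign)}
    phis = {c: sample_phi(members) for c, members in clusters.items()}

    alpha_dp = 1.0
    alpha_trace = []
    co = np.zeros((n_mut, n_mut))
    n_kept = 0
    next_id = max(clusters) + 1

    for it in range(mcmc.iterations):
        order = range(n_mut)
        for i in order:
            c_old = assign[i]
            clusters[c_old].remove(i)
            if not clusters[c_old]:
                del clusters[c_old]
                del phis[c_old]
            cids = list(clusters)
            phi_mat = np.vstack([phis[c] for c in cids]) if cids else np.empty((0, n_reg))
            logw = np.empty(len(cids) + 1)
            if cids:
                sizes = np.array([len(clusters[c]) for c in cids], dtype=float)
                logw[:-1] = np.log(sizes) + obs_loglik(i, phi_mat)
            logw[-1] = np.log(alpha_dp) + log_pred[i]
            w = np.exp(logw - logw.max())
            w /= w.sum()
            choice = rng.choice(len(w), p=w)
            if choice == len(cids):
                c_new = next_id
                next_id += 1
                clusters[c_new] = [i]
                phis[c_new] = sample_phi([i])
            else:
                c_new = cids[choice]
                clusters[c_new].append(i)
            assign[i] = c_new
        for c in clusters:
            phis[c] = sample_phi(clusters[c])
        alpha_dp = _sample_alpha_dp(alpha_dp, n_mut, len(clusters), alpha_prior, rng)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            same = assign[:, None] == assign[None, :]
            co += same
            n_kept += 1
            alpha_trace.append(alpha_dp)

    sim = co / max(n_kept, 1)
    np.fill_diagonal(sim, 1.0)
    sim_df = pd.DataFrame(sim, index=mut_ids, columns=mut_ids)

    if n_mut == 1:
        consensus = np.array([1])
    else:
        dist = squareform(1 - sim, checks=False)
        z = linkage(dist, method="average")
        consensus = fcluster(z, t=0.5, criterion="distance")

    out_clusters = {}
    for cid in sorted(set(consensus)):
        members = [mut_ids[i] for i in range(n_mut) if consensus[i] == cid]
        midx = [mi[m] for m in members]
        ccf = {}
        for r, j in ri.items():
            obs_i = [i for i in midx if seen[i, j]]
            if obs_i:
                vals = np.clip(k[obs_i, j] / np.maximum(n[obs_i, j], 1) / a[obs_i, j], 0, 1)
                ccf[r] = float(vals.mean())
            else:
                ccf[r] = None
        out_clusters[int(cid)] = {"ccf": ccf, "members": members}

    result = CloneClusterSet(
        clusters=out_clusters,
        similarity=sim_df,
        alpha_dp_mean=float(np.mean(alpha_trace)) if alpha_trace else alpha_dp,
        settings=mcmc,
    )
    classify_clonality(result)
    return result


def classify_clonality(clusters: CloneClusterSet, tie_tolerance: float = 0.9) -> dict:
    """Label clusters major vs sub-clonal (in place; also returned).

    The major clone is the cluster with the highest mean CCF across regions;
    any cluster within ``tie_tolerance`` (default 0.9x) of that maximum is
    co-labelled major, the rest are sub-clonal.
    """
    if not clusters.clusters:
        raise ValueError("no clusters to classify")
    means = {
        cid: np.mean([v for v in info["ccf"].values() if v is not None] or [0.0])
        for cid, info in clusters.clusters.items()
    }
    top = max(means.values())
    labels = {
        cid: ("major" if top > 0 and mu >= tie_tolerance * top else "sub-clonal")
        for cid, mu in means.items()
    }
    if top == 0:
        labels[max(means, key=means.get)] = "major"
    clusters.labels = labels
    return labels


def clusters_to_frame(clusters: CloneClusterSet) -> pd.DataFrame:
    """Flat TSV-ready table: one row per (cluster, member)."""
    rows = []
    for cid, info in clusters.clusters.items():
        for m in info["members"]:
            row = {"cluster": cid, "mutation_id": m,
                   "clonality": clusters.labels.get(cid, "")}
            for r, v in info["ccf"].items():
                row[f"ccf_{r}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
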