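"""Synthetic multi-region tumour sequencing data.

Generates clone trees with region-wise cancer-cell fractions (CCFs), binomial
SNV read counts at exome (~100x) or ultra-deep validation (~500x) depth, and
SNP-array-like probe tables (logR/BAF) with haplotype-phased arm-level copy
number events.  Every stage of the downstream analysis pipeline can be
exercised against the ground truth returned here, without any external data.

The generative model:

* A rooted clone tree.  The founding clone has CCF 1 in every region that
  contains tumour; each region's clone CCFs are produced by stick-breaking the
  parent's CCF among its children, which guarantees the phylogenetic sum rule
  (parent CCF >= sum of child CCFs) by construction.
* SNVs are assigned to clones; the expected variant allele frequency of a
  mutation with multiplicity ``m`` on total copy number ``q`` in a region with
  purity ``a`` and clone CCF ``f`` is ``a*f*m / (a*q + 2*(1-a))``.  Sequencing
  depth is Poisson around the platform mean (truncated at >= 1 read) and alt
  counts are binomial.
* Arm-level SCNAs are placed on a named haplotype (A or B) of a clone; probe
  logR reflects the purity- and CCF-weighted total copy number, and the BAF of
  heterozygous germline probes reflects the phase of the affected haplotype, so
  mirrored allelic imbalance between regions is reproducible.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, giving reproducible independent
sub-streams per tumour and per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CloneTree",
    "ScnaEvent",
    "default_arm_table",
    "simulate_clone_tree",
    "simulate_variant_counts",
    "simulate_snp_array",
    "simulate_cohort",
]

#: arm lengths (bp) of the synthetic genome used when no cytoband table is
#: supplied: 6 chromosomes with unequal p/q arms, enough structure to exercise
#: arm-level calling without hg19-scale probe counts.
_DEFAULT_N_CHROMS = 6
_DEFAULT_P_LEN = 40_000_000
_DEFAULT_Q_LEN = 60_000_000


class SimulationError(ValueError):
    """Invalid simulation parameters or inconsistent ground truth."""


class ConfigError(KeyError):
    """A scenario configuration is missing a required key."""


@dataclass
class ScnaEvent:
    """An arm-level copy number event carried by one clone.

    direction is +1 for a single-copy gain, -1 for a single-copy loss;
    haplotype names the affected parental allele ('A' or 'B').
    """

    event_id: str
    clone: int
    chrom: str
    arm: str  # 'p' | 'q' | 'pq' (whole chromosome)
    direction: int
    haplotype: str

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise SimulationError(f"direction must be +-1, got {self.direction}")
        if self.haplotype not in ("A", "B"):
            raise SimulationError(f"haplotype must be 'A' or 'B', got {self.haplotype!r}")


@dataclass
class CloneTree:
    """Ground-truth clone tree for one simulated tumour.

    parents[i] is the parent clone of clone i (None for the root, clone 0).
    clone_ccf is a (n_clones, n_regions) matrix of cancer-cell fractions.
    mutation_assignment maps mutation ids to clone ids; it starts empty and is
    filled in by :func:`simulate_variant_counts`.
    """

    parents: list
    clone_ccf: np.ndarray
    purity: np.ndarray
    region_ids: list
    seed: int
    mutation_assignment: dict = field(default_factory=dict)
    scna_events: list = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    @property
    def n_regions(self) -> int:
        return self.clone_ccf.shape[1]

    def children(self, clone: int) -> list:
        return [i for i, p in enumerate(self.parents) if p == clone]

    def validate(self, atol: float = 1e-9) -> None:
        """Check the phylogenetic sum rule and value ranges; raise on failure."""
        ccf = self.clone_ccf
        if ccf.shape[0] != len(self.parents):
            raise SimulationError("clone_ccf rows must match number of clones")
        if np.any(ccf < -atol) or np.any(ccf > 1 + atol):
            raise SimulationError("CCFs must lie in [0, 1]")
        if not np.allclose(ccf[0], 1.0, atol=atol):
            raise SimulationError("root clone must have CCF 1 in every region")
        if np.any(self.purity <= 0) or np.any(self.purity > 1):
            raise SimulationError("purity must lie in (0, 1]")
        for v in range(self.n_clones):
            kids = self.children(v)
            if kids:
                child_sum = ccf[kids].sum(axis=0)
                if np.any(child_sum > ccf[v] + atol):
                    raise SimulationError(
                        f"tree constraint violated at clone {v}: "
                        f"children CCF sum exceeds parent CCF"
                    )


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-stream: one root seed, spawn-keyed children."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def simulate_clone_tree(
    n_clones: int,
    n_regions: int,
    purity_range: tuple = (0.3, 0.9),
    seed: int = 0,
    p_clone_absent: float = 0.25,
) -> CloneTree:
    """Draw a random rooted clone tree with region-wise CCFs.

    Each non-root clone attaches to a uniformly chosen existing clone.  Per
    region, a clone may be entirely absent (probability ``p_clone_absent``,
    together with its whole subtree), which creates the region-private
    mutation blocks that multi-region sequencing detects; present children
    share their parent's CCF by symmetric stick-breaking (Dirichlet weights),
    so the tree constraint holds exactly.  Deterministic for a fixed seed.
    """
    if n_clones < 1 or n_regions < 1:
        raise SimulationError("n_clones and n_regions must be >= 1")
    lo, hi = purity_range
    if not (0 < lo <= hi <= 1):
        raise SimulationError(f"purity_range must satisfy 0 < lo <= hi <= 1, got {purity_range}")

    rng = _rng_for(seed, 0)
    parents: list = [None]
    for i in range(1, n_clones):
        parents.append(int(rng.integers(0, i)))

    purity = rng.uniform(lo, hi, size=n_regions)

    ccf = np.zeros((n_clones, n_regions))
    ccf[0, :] = 1.0
    children = [[] for _ in range(n_clones)]
    for i, p in enumerate(parents):
        if p is not None:
            children[p].append(i)

    for r in range(n_regions):
        absent = np.zeros(n_clones, dtype=bool)
        for i in range(1, n_clones):
            if absent[parents[i]] or rng.random() < p_clone_absent:
                absent[i] = True
        # breadth-first stick-breaking of each parent's CCF among present kids
        stack = [0]
        while stack:
            v = stack.pop()
            kids = [c for c in children[v] if not absent[c]]
            if kids:
                # one extra stick keeps mass with the parent's own cells
                w = rng.dirichlet(np.ones(len(kids) + 1))
                for c, frac in zip(kids, w[:-1]):
                    ccf[c, r] = ccf[v, r] * frac
            stack.extend(kids)

    tree = CloneTree(
        parents=parents,
        clone_ccf=ccf,
        purity=purity,
        region_ids=[f"R{r + 1}" for r in range(n_regions)],
        seed=seed,
    )
    tree.validate()
    return tree


def assign_scna_events(tree: CloneTree, menu: list, seed: int | None = None) -> None:
    """Attach arm-level SCNA events to the tree.

    ``menu`` items are dicts with keys chrom, arm ('p'|'q'|'pq'), direction
    (+1|-1) and optionally clone and haplotype; unspecified clones/haplotypes
    are drawn at random from the tree's own seed stream.
    """
    rng = _rng_for(tree.seed if seed is None else seed, 3)
    for j, item in enumerate(menu):
        clone = item.get("clone")
        if clone is None:
            clone = int(rng.integers(0, tree.n_clones))
        hap = item.get("haplotype")
        if hap is None:
            hap = "A" if rng.random() < 0.5 else "B"
        tree.scna_events.append(
            ScnaEvent(
                event_id=item.get("event_id", f"scna{j}"),
                clone=int(clone),
                chrom=str(item["chrom"]),
                arm=str(item.get("arm", "pq")),
                direction=int(item["direction"]),
                haplotype=hap,
            )
        )


def simulate_variant_counts(
    tree: CloneTree,
    n_snvs: int,
    depth: float,
    platform: str = "exome",
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit per-region read counts for ``n_snvs`` somatic SNVs.

    Each SNV is assigned uniformly to a clone (recorded in
    ``tree.mutation_assignment``).  Copy number q=2 and multiplicity m=1 are
    used unless the SNV falls on an arm carrying a clonal gain on the same
    haplotype, in which case the truth columns record the adjusted (q, m).
    Returns a long-format table with one row per mutation x region and truth
    columns (clone, ccf, expected_vaf, q, m).
    """
    if platform not in ("exome", "deep"):
        raise SimulationError(f"platform must be 'exome' or 'deep', got {platform!r}")
    if depth <= 0:
        raise SimulationError("depth must be > 0")
    tree.validate()
    if n_snvs == 0:
        return pd.DataFrame(
            columns=[
                "mutation_id", "chrom", "pos", "ref", "alt", "region",
                "depth", "alt_count", "clone", "ccf", "expected_vaf", "q", "m",
            ]
        )

    rng = _rng_for(tree.seed if seed is None else seed, 1 if platform == "exome" else 2)
    bases = np.array(list("ACGT"))
    n_chrom = _DEFAULT_N_CHROMS
    chroms = np.array([f"chr{c}" for c in rng.integers(1, n_chrom + 1, size=n_snvs)])
    positions = np.sort(rng.choice(90_000_000, size=n_snvs, replace=False)) + 1
    refs = bases[rng.integers(0, 4, size=n_snvs)]
    alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
    clones = rng.integers(0, tree.n_clones, size=n_snvs)

    rows = []
    for i in range(n_snvs):
        mut_id = f"M{i + 1:04d}"
        tree.mutation_assignment[mut_id] = int(clones[i])
        q, m = 2, 1
        for r, region in enumerate(tree.region_ids):
            alpha = tree.purity[r]
            f = tree.clone_ccf[clones[i], r]
            evaf = alpha * f * m / (alpha * q + 2 * (1 - alpha))
            d = 0
            while d < 1:  # Poisson truncated at >=1 read
                d = int(rng.poisson(depth))
            k = int(rng.binomial(d, evaf))
            rows.append(
                (mut_id, chroms[i], int(positions[i]), refs[i], alts[i], region,
                 d, k, int(clones[i]), f, evaf, q, m)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "mutation_id", "chrom", "pos", "ref", "alt", "region",
            "depth", "alt_count", "clone", "ccf", "expected_vaf", "q", "m",
        ],
    )
    out.attrs["platform"] = platform
    out.attrs["mean_depth"] = depth
    return out


def default_arm_table(
    n_chroms: int = _DEFAULT_N_CHROMS,
    p_len: int = _DEFAULT_P_LEN,
    q_len: int = _DEFAULT_Q_LEN,
) -> pd.DataFrame:
    """Arm coordinate table (chrom, arm, start, end; 0-based half-open) for
    the synthetic genome."""
    rows = []
    for c in range(1, n_chroms + 1):
        rows.append((f"chr{c}", "p", 0, p_len))
        rows.append((f"chr{c}", "q", p_len, p_len + q_len))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])


def _event_arms(ev: ScnaEvent) -> list:
    return ["p", "q"] if ev.arm == "pq" else [ev.arm]


def simulate_snp_array(
    tree: CloneTree,
    n_probes_per_arm: int = 60,
    noise_sd: float = 0.05,
    seed: int | None = None,
    arm_table: pd.DataFrame | None = None,
    het_fraction: float = 0.4,
) -> pd.DataFrame:
    """Probe-level logR/BAF table for every region of the tree.

    Expected logR of a probe is ``log2((a*qbar + 2*(1-a)) / 2)`` where ``qbar``
    is the CCF-weighted mean total copy number over tumour cells; Gaussian
    noise of sd ``noise_sd`` is added to logR and (half that) to BAF.  The BAF
    of heterozygous germline probes follows the phase of the affected
    haplotype: probes whose B allele sits on the gained haplotype shift above
    0.5, the rest below, so mirrored imbalance between regions is visible.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    tree.validate()
    if arm_table is None:
        arm_table = default_arm_table()
    rng = _rng_for(tree.seed if seed is None else seed, 4)

    # germline phase and het status are properties of the patient, not region
    probes = []
    for _, arm_row in arm_table.iterrows():
        pos = np.linspace(arm_row.start, arm_row.end - 1, n_probes_per_arm).astype(int)
        for j, p in enumerate(pos):
            probes.append((f"{arm_row.chrom}{arm_row.arm}_{j:04d}", arm_row.chrom,
                           arm_row.arm, int(p)))
    probe_df = pd.DataFrame(probes, columns=["probe_id", "chrom", "arm", "pos"])
    n_probes = len(probe_df)
    is_het = rng.random(n_probes) < het_fraction
    b_on_hap_a = rng.random(n_probes) < 0.5  # germline phase of the B allele

    rows = []
    for r, region in enumerate(tree.region_ids):
        alpha = tree.purity[r]
        # per-haplotype mean copy number over tumour cells, per (chrom, arm)
        hap_cn = {}
        for _, arm_row in arm_table.iterrows():
            n_a, n_b = 1.0, 1.0
            for ev in tree.scna_events:
                if ev.chrom == arm_row.chrom and arm_row.arm in _event_arms(ev):
                    f = tree.clone_ccf[ev.clone, r]
                    if ev.haplotype == "A":
                        n_a += ev.direction * f
                    else:
                        n_b += ev.direction * f
            hap_cn[(arm_row.chrom, arm_row.arm)] = (max(n_a, 0.0), max(n_b, 0.0))

        for i in range(n_probes):
            chrom, arm = probe_df.chrom.iloc[i], probe_df.arm.iloc[i]
            n_a, n_b = hap_cn[(chrom, arm)]
            total = alpha * (n_a + n_b) + 2 * (1 - alpha)
            logr = np.log2(total / 2.0)
            if noise_sd > 0:
                logr += rng.normal(0, noise_sd)
            if is_het[i]:
                b_copies = alpha * (n_a if b_on_hap_a[i] else n_b) + (1 - alpha)
                baf = b_copies / total
                if noise_sd > 0:
                    baf += rng.normal(0, noise_sd / 2)
                baf = float(np.clip(baf, 0.0, 1.0))
            else:
                baf = np.nan
            rows.append(
                (probe_df.probe_id.iloc[i], chrom, int(probe_df.pos.iloc[i]),
                 region, float(logr), baf, bool(is_het[i]))
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "region", "logR", "BAF", "is_het_germline"]
    )


_REQUIRED_CONFIG_KEYS = ("n_tumours", "n_regions", "clone_range", "n_snvs", "depth")


def simulate_cohort(config: dict, seed: int = 0) -> list:
    """One-call fixture factory: a list of per-tumour bundles.

    ``config`` must name n_tumours, n_regions, clone_range (inclusive pair),
    n_snvs and depth; optional keys: deep_depth (default 500), purity_range,
    scna_menu, n_probes_per_arm, noise_sd, p_clone_absent.  Each bundle is a
    dict with the clone tree, exome and deep read-count tables, probe table
    and a machine-readable truth dict.  Deterministic for fixed (config, seed).
    """
    for key in _REQUIRED_CONFIG_KEYS:
        if key not in config:
            raise ConfigError(f"scenario config is missing required key {key!r}")
    lo, hi = config["clone_range"]
    ss = np.random.SeedSequence(seed)
    tumour_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config["n_tumours"])]

    bundles = []
    for t, tseed in enumerate(tumour_seeds):
        rng = _rng_for(tseed, 9)
        n_clones = int(rng.integers(lo, hi + 1))
        tree = simulate_clone_tree(
            n_clones=n_clones,
            n_regions=config["n_regions"],
            purity_range=tuple(config.get("purity_range", (0.3, 0.9))),
            seed=tseed,
            p_clone_absent=config.get("p_clone_absent", 0.25),
        )
        if config.get("scna_menu"):
            assign_scna_events(tree, config["scna_menu"])
        exome = simulate_variant_counts(tree, config["n_snvs"], config["depth"], "exome")
        # deep platform re-measures the same loci at validation depth
        deep = _remeasure(tree, exome, config.get("deep_depth", 500))
        probe_table = simulate_snp_array(
            tree,
            n_probes_per_arm=config.get("n_probes_per_arm", 60),
            noise_sd=config.get("noise_sd", 0.05),
        )
        truth = {
            "tumour": f"T{t + 1}",
            "n_clones": tree.n_clones,
            "parents": [(-1 if p is None else p) for p in tree.parents],
            "purity": tree.purity.tolist(),
            "clone_ccf": tree.clone_ccf.tolist(),
            "mutation_assignment": dict(tree.mutation_assignment),
            "scna_events": [vars(e) for e in tree.scna_events],
            "seed": tseed,
        }
        bundles.append(
            {"tumour": f"T{t + 1}", "tree": tree, "exome": exome, "deep": deep,
             "probes": probe_table, "truth": truth}
        )
    return bundles


def _remeasure(tree: CloneTree, counts: pd.DataFrame, depth: float) -> pd.DataFrame:
    """Re-sequence the loci of an existing count table at a new depth
    (ultra-deep validation of exome-discovered mutations)."""
    rng = _rng_for(tree.seed, 2)
    out = counts.copy()
    new_d, new_k = [], []
    for evaf in out["expected_vaf"]:
        d = 0
        while d < 1:
            d = int(rng.poisson(depth))
        new_d.append(d)
        new_k.append(int(rng.binomial(d, evaf)))
    out["depth"] = new_d
    out["alt_count"] = new_k
    out.attrs["platform"] = "deep"
    out.attrs["mean_depth"] = depth
    return out
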