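"""Synthetic two-kingdom reactor community time series with known truth.

The generator emulates a sequencing-batch reactor granulation experiment:
~52 time points spanning a floccular, an intermediate and a granular stage,
one 16S-like prokaryote table and one 18S-like eukaryote table at realistic
rarefaction depths, a rooted ultrametric phylogeny per kingdom, and a
metadata table with a one-dimensional latent reactor state expressed as
several noisy measured covariates (nitrate, VSS, phosphate, TOC).

Community dynamics follow a discrete-time replicator-with-immigration
recurrence. ASV i has a Gaussian fitness kernel around its environmental
optimum o_i: w_i(t) = exp(-(E_t - o_i)^2 / (2 sigma_sel^2)); the expected
composition at t is (1 - m) * normalized(x_{t-1} * w(t)) + m * pool, and
the observed counts are a multinomial draw at the kingdom's read depth, so
drift is encoded purely by finite sampling depth. Optima evolve by Brownian
motion on the tree (rate lambda), making environmental preferences
phylogenetically conserved; tips are binned into guilds whose optima
center on successive stage means, so guilds dominate successively.
Eukaryote fitness can additionally be coupled to the realized relative
abundance of the same-numbered prokaryote guild (strength kappa), planting
true positive inter-kingdom associations. All ground truth (guilds, optima,
coupled guild pairs, per-stage regime) is recorded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountTable, EnvTable, PhyloTree, assign_stage, STAGES

__all__ = [
    "Scenario",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_phylo_traits",
    "simulate_reactor_series",
    "preset_scenario",
    "toy_fixture",
]

#: Latent reactor state mean per stage (dimensionless "granulation axis").
STAGE_MEANS = {"floccular": 0.0, "intermediate": 1.0, "granular": 2.0}

#: sigma_sel at or below this value counts as a selection regime in truth.
SELECTION_SIGMA_THRESHOLD = 1.0


def _default_days():
    """52 sampling days spanning the three stages (denser early)."""
    floc = np.arange(0, 16, 2)  # 8 samples, days 0..14
    inter = np.linspace(16, 112, 18)  # 18 samples
    gran = np.linspace(116, 343, 26)  # 26 samples
    return np.round(np.concatenate([floc, inter, gran])).astype(float)


@dataclass
class Scenario:
    """Generator configuration; defaults reproduce the study conditions."""

    n_samples: int = 52
    days: np.ndarray = field(default_factory=_default_days)
    n_asvs: tuple = (411, 125)  # (prokaryote, eukaryote)
    read_depth: tuple = (43329, 31420)
    # selection strength per stage (floccular, intermediate, granular);
    # small = strong selection, very large = neutral
    sigma_sel: tuple = (0.35, 0.55, 1.4)
    immigration: float = 0.05
    trait_signal: float = 1.0  # Brownian-motion rate for optima
    coupling: float = 0.0  # prokaryote -> eukaryote fitness coupling
    n_guilds: int = 3
    env_noise: float = 0.15
    env_profile: str = "stagewise"  # or "constant"
    env_constant_value: float = 1.0
    # sd of per-ASV, per-time lognormal fitness fluctuations: members of the
    # selected niche exchange dominance while the niche itself is stable
    fitness_noise: float = 0.5
    # terminal cluster structure of the trees: ASVs per species cluster,
    # within-cluster tip depth (sequence-variant tufts of real phylogenies)
    # and mean extra terminal branch length (ML trees are not ultrametric)
    cluster_size: int = 4
    cluster_depth: float = 0.02
    tip_extension: float = 0.4
    guild_depth: float = 0.5
    pool_sigma: float = 1.0  # lognormal sd of species pool abundances
    seed: int = 0

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        if self.n_samples != len(self.days):
            raise ValueError("n_samples must equal the number of days")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        for s in self.sigma_sel:
            if s <= 0:
                raise ValueError("sigma_sel must be positive (0 is degenerate delta selection)")
        if not 0 <= self.immigration <= 1:
            raise ValueError("immigration rate must lie in [0, 1]")
        if self.trait_signal < 0 or self.coupling < 0:
            raise ValueError("rates must be non-negative")
        if self.env_profile not in ("stagewise", "constant"):
            raise ValueError("env_profile must be 'stagewise' or 'constant'")

    def sigma_for_stage(self, stage: str) -> float:
        return float(self.sigma_sel[STAGES.index(stage)])


@dataclass
class SyntheticDataset:
    """Generated tables, trees, metadata and ground truth."""

    prok_table: CountTable
    euk_table: CountTable
    prok_tree: PhyloTree
    euk_tree: PhyloTree
    env: EnvTable
    truth: dict  # asv_truth DataFrame, coupled_guilds, stage_regime

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.prok_table.to_tsv(outdir / "prok_counts.tsv")
        self.euk_table.to_tsv(outdir / "euk_counts.tsv")
        self.prok_tree.to_newick(outdir / "prok_tree.nwk")
        self.euk_tree.to_newick(outdir / "euk_tree.nwk")
        self.env.to_csv(outdir / "metadata.csv")
        self.truth["asv_truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ----------------------------------------------------------------------
# tree + traits
# ----------------------------------------------------------------------
class _Node:
    __slots__ = ("children", "birth", "length", "name")

    def __init__(self, birth):
        self.children = []
        self.birth = birth
        self.length = 0.0
        self.name = None


def _yule_newick(
    n_tips: int,
    rng: np.random.Generator,
    prefix: str,
    start: int,
    depth: float,
    cluster_sizes=None,
    cluster_depth: float = 0.0,
    tip_extension: float = 0.0,
) -> tuple[str, int]:
    """Newick (no root length/semicolon) of a Yule tree scaled to ``depth``.

    Tips are named ``{prefix}{start:04d}`` onward; returns the string and
    the next free tip index. When ``cluster_sizes`` is given (one entry per
    Yule tip), each tip is expanded into a polytomy of that many ASV tips
    hanging ``cluster_depth`` below it — emulating tight clusters of
    sequence variants within a species/genus while staying ultrametric.
    """
    n_species = n_tips if cluster_sizes is None else len(cluster_sizes)
    if n_species == 1:
        k = 1 if cluster_sizes is None else cluster_sizes[0]
        if k == 1:
            return f"{prefix}{start:04d}", start + 1
        cd = min(cluster_depth, 0.5 * depth)
        names = ",".join(f"{prefix}{start + i:04d}:{cd:.10f}" for i in range(k))
        return f"(({names}):{depth - cd:.10f})", start + k
    t = 0.0
    root = _Node(0.0)
    active = [root]
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(len(active))
        node = active.pop(k)
        node.length = t - node.birth
        c1, c2 = _Node(t), _Node(t)
        node.children = [c1, c2]
        active.extend([c1, c2])
    t += rng.exponential(1.0 / n_species)
    for tip in active:
        tip.length = t - tip.birth
    # depth is measured below the first split; drop the stem
    scale = (t - root.length) / depth
    counter = [start]
    species = [0]

    def newick(node):
        if not node.children:
            length = node.length / scale
            if tip_extension > 0:
                # long terminal branches, as in substitution-rate ML trees
                length += tip_extension * rng.uniform(0.7, 1.3)
            k = 1 if cluster_sizes is None else cluster_sizes[species[0]]
            species[0] += 1
            if k == 1:
                name = f"{prefix}{counter[0]:04d}"
                counter[0] += 1
                return f"{name}:{length:.10f}"
            cd = min(cluster_depth, 0.5 * length)
            names = []
            for _ in range(k):
                names.append(f"{prefix}{counter[0]:04d}:{cd:.10f}")
                counter[0] += 1
            return f"({','.join(names)}):{length - cd:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.length / scale:.10f}"

    body = ",".join(newick(c) for c in root.children)
    return f"({body})", counter[0]


def simulate_tree(n_tips: int, seed: int | None = None, prefix: str = "T") -> PhyloTree:
    """Yule (pure-birth) ultrametric tree scaled to root-tip depth 1.

    Tips are named ``{prefix}0001`` .. in a deterministic traversal order;
    the same seed always yields the same newick string.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    s, _ = _yule_newick(n_tips, rng, prefix, 1, 1.0)
    return PhyloTree.from_newick(s + ";")


def _even_split(total: int, parts: int) -> list:
    base = total // parts
    return [base + (1 if i < total % parts else 0) for i in range(parts)]


def _guild_tree(
    n_tips: int,
    n_guilds: int,
    seed,
    prefix: str,
    guild_depth: float = 0.5,
    cluster_size: int = 1,
    cluster_depth: float = 0.04,
    tip_extension: float = 0.0,
    pool_sigma: float = 1.0,
) -> tuple[PhyloTree, np.ndarray]:
    """Kingdom tree: ``n_guilds`` balanced Yule clades joined at the root.

    Each guild is a monophyletic subtree of depth ``guild_depth`` on a stem
    of 1 - guild_depth, so within-guild distances are small relative to
    between-guild distances — deep lineages with conserved environmental
    preferences. With ``cluster_size`` > 1, guild members come in tight
    terminal clusters of near-identical ASVs (sequence variants of one
    species), the hallmark of real amplicon phylogenies. Returns the tree
    and the per-tip guild index (tip order).
    """
    if n_tips < 2 * n_guilds:
        raise ValueError("need at least 2 tips per guild")
    rng = np.random.default_rng(seed)
    sizes = _even_split(n_tips, n_guilds)
    parts, spans = [], []
    weight_by_name = np.empty(n_tips + 1)
    species_by_name = np.empty(n_tips + 1, dtype=int)
    species_counter = 0
    idx = 1
    for size in sizes:
        lo = idx
        if cluster_size > 1 and size >= 4:
            # abundant species carry disproportionately more sequence
            # variants (allocation ~ abundance^2): dominant taxa sit in
            # tight tufts while most species stay isolated singletons —
            # the hallmark of real amplicon phylogenies
            n_species = max(2, round(size * 0.8))
            ab = rng.lognormal(0.0, pool_sigma, n_species)
            raw = ab**2 / (ab**2).sum() * size
            k = np.maximum(1, np.floor(raw).astype(int))
            while k.sum() > size:
                k[np.argmax(k)] -= 1
            while k.sum() < size:
                k[np.argmax(raw - k)] += 1
            csizes = [int(v) for v in k]
            s, idx = _yule_newick(
                size, rng, prefix, idx, guild_depth,
                cluster_sizes=csizes, cluster_depth=cluster_depth,
                tip_extension=tip_extension,
            )
            # every variant of an abundant species is itself abundant
            w = np.repeat(ab, k)
            sp = np.repeat(species_counter + np.arange(n_species), k)
            species_counter += n_species
        else:
            s, idx = _yule_newick(
                size, rng, prefix, idx, guild_depth, tip_extension=tip_extension
            )
            w = rng.lognormal(0.0, pool_sigma, size)
            sp = species_counter + np.arange(size)
            species_counter += size
        weight_by_name[lo:idx] = w
        species_by_name[lo:idx] = sp
        parts.append(f"{s}:{1.0 - guild_depth:.10f}")
        spans.append((lo, idx))
    tree = PhyloTree.from_newick("(" + ",".join(parts) + ");")
    pos = {name: i for i, name in enumerate(tree.tip_names())}
    guild = np.empty(n_tips, dtype=int)
    pool_weight = np.empty(n_tips)
    species = np.empty(n_tips, dtype=int)
    for g, (lo, hi) in enumerate(spans):
        for k in range(lo, hi):
            p = pos[f"{prefix}{k:04d}"]
            guild[p] = g
            pool_weight[p] = weight_by_name[k]
            species[p] = species_by_name[k]
    return tree, guild, pool_weight, species


def simulate_phylo_traits(
    tree: PhyloTree, rate: float, seed: int | None = None, root_value: float = 0.0
) -> pd.Series:
    """Brownian-motion trait values at the tips.

    Child value = parent value + Normal(0, sqrt(rate * branch_length));
    rate 0 returns the root value at every tip.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    values = {id(tree.tree): root_value}
    out = {}
    for node in tree.tree.preorder(include_self=False):
        bl = node.length or 0.0
        v = values[id(node.parent)] + (
            rng.normal(0.0, np.sqrt(rate * bl)) if rate > 0 and bl > 0 else 0.0
        )
        values[id(node)] = v
        if node.is_tip():
            out[node.name] = v
    tips = [tp.name for tp in tree.tree.tips()]
    return pd.Series([out[n] for n in tips], index=tips, name="trait")


# ----------------------------------------------------------------------
# reactor series
# ----------------------------------------------------------------------
def _environment(scenario: Scenario, rng: np.random.Generator):
    stages = [assign_stage(d) for d in scenario.days]
    if scenario.env_profile == "constant":
        latent = np.full(scenario.n_samples, scenario.env_constant_value)
    else:
        latent = np.array([STAGE_MEANS[s] for s in stages], dtype=float)
    latent = latent + rng.normal(0.0, scenario.env_noise, scenario.n_samples)
    cov = pd.DataFrame(
        {
            "nitrate": 2.0 + 12.0 * latent + rng.normal(0, 1.0, scenario.n_samples),
            "vss": 1.5 + 3.0 * latent + rng.normal(0, 0.4, scenario.n_samples),
            "phosphate": 30.0 - 8.0 * latent + rng.normal(0, 1.5, scenario.n_samples),
            "toc": 18.0 - 3.0 * latent + rng.normal(0, 1.0, scenario.n_samples),
        }
    )
    return latent, stages, cov


def _optima_from_guilds(trait, guild: "np.ndarray", n_guilds: int, pool_weight=None):
    """Optima centered on successive stage means, one center per guild.

    Within a guild the Brownian trait adds a conserved fine-scale spread
    around the guild's stage-mean optimum, so environmental preferences
    are phylogenetically conserved at both the guild and the tip scale.
    When pool weights are given, abundant (variant-rich) species sit
    closest to the guild optimum — dominance and niche fit co-occur, as
    for the granule-forming lineages of real reactors.
    """
    z = trait.to_numpy()
    stage_axis = np.array([STAGE_MEANS[s] for s in STAGES])
    centers = np.interp(
        np.linspace(0, len(stage_axis) - 1, n_guilds),
        np.arange(len(stage_axis)),
        stage_axis,
    )
    optimum = np.empty(len(z))
    for g in range(n_guilds):
        sel = guild == g
        zz = z[sel]
        spread = (zz - zz.mean()) / (zz.std() + 1e-9) * 0.25
        if pool_weight is not None:
            w = pool_weight[sel]
            q = np.argsort(np.argsort(-w)) / max(len(w) - 1, 1)  # 0 = most abundant
            spread = spread * (0.2 + 1.3 * q)
        optimum[sel] = centers[g] + spread
    return optimum


def _simulate_kingdom(
    scenario: Scenario,
    kingdom: str,
    n_asvs: int,
    depth: int,
    stages,
    latent,
    rng: np.random.Generator,
    tree_seed: int,
    trait_seed: int,
    coupling_share=None,  # (n_samples, n_guilds) prokaryote guild shares
    guild_of_euk=None,
):
    prefix = "P" if kingdom == "prokaryote" else "E"
    tree, guild, pool_weight, species = _guild_tree(
        n_asvs,
        scenario.n_guilds,
        tree_seed,
        prefix,
        cluster_size=scenario.cluster_size,
        cluster_depth=scenario.cluster_depth,
        tip_extension=scenario.tip_extension,
        guild_depth=scenario.guild_depth,
        pool_sigma=scenario.pool_sigma,
    )
    trait = simulate_phylo_traits(tree, scenario.trait_signal, seed=trait_seed)
    optimum = _optima_from_guilds(trait, guild, scenario.n_guilds, pool_weight)
    asv_ids = list(trait.index)
    # immigration pool: heavy-tailed, species-structured, fixed through time
    pool = pool_weight * rng.lognormal(0.0, 0.3, n_asvs)
    pool /= pool.sum()
    x = pool.copy()
    counts = np.empty((scenario.n_samples, n_asvs), dtype=np.int64)
    m = scenario.immigration
    for tstep in range(scenario.n_samples):
        sigma = scenario.sigma_for_stage(stages[tstep])
        w = np.exp(-((latent[tstep] - optimum) ** 2) / (2.0 * sigma**2))
        if scenario.fitness_noise > 0:
            # lottery noise acts at the species level: all sequence variants
            # of a species share each temporal fitness fluctuation
            n_species_total = species.max() + 1
            w = w * np.exp(rng.normal(0.0, scenario.fitness_noise, n_species_total))[species]
        if coupling_share is not None and scenario.coupling > 0:
            w = w * (1.0 + scenario.coupling * coupling_share[tstep, guild])
        fit = x * w
        s = fit.sum()
        if s <= 0:
            fit = pool.copy()
            s = fit.sum()
        expected = (1.0 - m) * fit / s + m * pool
        counts[tstep] = rng.multinomial(depth, expected / expected.sum())
        x = counts[tstep] / depth
    table = CountTable(
        [f"S{t + 1:02d}" for t in range(scenario.n_samples)],
        asv_ids,
        counts,
        kingdom=kingdom,
        days=scenario.days,
    )
    truth = pd.DataFrame(
        {
            "asv_id": asv_ids,
            "kingdom": kingdom,
            "guild": guild + 1,
            "optimum": optimum,
            "trait": trait.to_numpy(),
        }
    )
    return table, tree, truth, guild


def simulate_reactor_series(scenario: Scenario) -> SyntheticDataset:
    """Generate a full two-kingdom dataset from a scenario.

    The prokaryote community is simulated first; when ``coupling`` (kappa)
    is positive, each eukaryote ASV's fitness is multiplied by
    (1 + kappa * realized relative abundance of its same-numbered
    prokaryote guild), planting true positive inter-kingdom associations.
    """
    ss = np.random.SeedSequence(scenario.seed)
    seeds = ss.spawn(6)
    rng_env = np.random.default_rng(seeds[0])
    latent, stages, cov = _environment(scenario, rng_env)
    rng_p = np.random.default_rng(seeds[1])
    prok_table, prok_tree, prok_truth, prok_guild = _simulate_kingdom(
        scenario,
        "prokaryote",
        scenario.n_asvs[0],
        scenario.read_depth[0],
        stages,
        latent,
        rng_p,
        tree_seed=int(seeds[2].generate_state(1)[0] % (2**31)),
        trait_seed=int(seeds[3].generate_state(1)[0] % (2**31)),
    )
    # realized per-guild prokaryote relative-abundance shares
    rel = prok_table.relative_abundance()
    guild_share = np.zeros((scenario.n_samples, scenario.n_guilds))
    for g in range(scenario.n_guilds):
        guild_share[:, g] = rel[:, prok_guild == g].sum(axis=1)
    rng_e = np.random.default_rng(seeds[4])
    euk_table, euk_tree, euk_truth, _ = _simulate_kingdom(
        scenario,
        "eukaryote",
        scenario.n_asvs[1],
        scenario.read_depth[1],
        stages,
        latent,
        rng_e,
        tree_seed=int(seeds[5].generate_state(1)[0] % (2**31)),
        trait_seed=int(seeds[5].generate_state(2)[1] % (2**31)),
        coupling_share=guild_share if scenario.coupling > 0 else None,
    )
    env = EnvTable(
        pd.DataFrame(
            {
                "day": scenario.days,
                "stage": stages,
                "latent_state": latent,
                **{c: cov[c].to_numpy() for c in cov.columns},
            },
            index=prok_table.sample_ids,
        )
    )
    coupled = (
        [
            {"euk_guild": g + 1, "prok_guild": g + 1}
            for g in range(scenario.n_guilds)
        ]
        if scenario.coupling > 0
        else []
    )
    regime = {
        s: ("selection" if scenario.sigma_for_stage(s) <= SELECTION_SIGMA_THRESHOLD else "drift")
        for s in STAGES
    }
    truth = {
        "asv_truth": pd.concat([prok_truth, euk_truth], ignore_index=True),
        "coupled_guilds": coupled,
        "stage_regime": regime,
        "scenario": scenario,
    }
    return SyntheticDataset(prok_table, euk_table, prok_tree, euk_tree, env, truth)


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------
def preset_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Named study conditions.

    - ``paper_like``: the full study design — 52 samples over three stages,
      411/125 ASVs, read depths 43329/31420, selection strongest early and
      relaxing in the granular stage, moderate inter-kingdom coupling.
    - ``selection``: strong stable environmental filtering (constant
      environment, small sigma_sel) — deterministic assembly signatures.
    - ``neutral``: selection switched off (huge sigma_sel), strong
      immigration, shallow depth — drift signatures.
    - ``coupled``: compact scenario with a strong prokaryote->eukaryote
      guild coupling for bipartite-detection experiments.
    """
    presets = {
        "paper_like": dict(
            # universe large and skewed enough that the 10%/0.1% network
            # filter retains a few hundred ASVs per kingdom, as in the study
            n_asvs=(2000, 550),
            pool_sigma=1.8,
            sigma_sel=(0.25, 0.55, 4.0),
            fitness_noise=0.25,
            env_noise=0.08,
            immigration=0.025,
            coupling=1.5,
        ),
        "selection": dict(
            n_samples=30,
            days=np.arange(0, 300, 10, dtype=float),
            n_asvs=(411, 125),
            read_depth=(1500, 1050),
            sigma_sel=(0.35, 0.35, 0.35),
            immigration=0.06,
            fitness_noise=0.75,
            env_profile="constant",
            env_constant_value=0.0,
            tip_extension=0.7,
            cluster_depth=0.01,
            guild_depth=0.3,
        ),
        "neutral": dict(
            n_samples=30,
            days=np.arange(0, 300, 10, dtype=float),
            n_asvs=(90, 45),
            read_depth=(1200, 900),
            sigma_sel=(1e6, 1e6, 1e6),
            immigration=0.95,
            fitness_noise=0.0,
            cluster_size=1,  # phylogenetically random pool
            pool_sigma=0.5,
        ),
        "coupled": dict(
            n_samples=40,
            days=np.linspace(0, 340, 40),
            n_asvs=(30, 16),
            read_depth=(3000, 2000),
            sigma_sel=(0.8, 0.8, 0.8),
            immigration=0.1,
            fitness_noise=0.0,
            coupling=6.0,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = {**presets[name], **overrides, "seed": seed}
    return Scenario(**kwargs)


# ----------------------------------------------------------------------
# toy fixture
# ----------------------------------------------------------------------
def toy_fixture() -> SyntheticDataset:
    """Deterministic 6-sample, 8-ASV-per-kingdom miniature dataset.

    Hand-written counts (no RNG): sample 1 contains all 8 ASVs of each
    kingdom; later samples lose the early guild and gain the late one,
    giving a tiny but realistic succession for unit tests and docs.
    """
    days = np.array([0.0, 10.0, 30.0, 60.0, 150.0, 300.0])
    samples = [f"S{t + 1:02d}" for t in range(6)]

    def table(prefix, kingdom):
        asvs = [f"{prefix}{k + 1:04d}" for k in range(8)]
        counts = np.array(
            [
                [30, 25, 20, 10, 6, 4, 3, 2],
                [22, 28, 18, 12, 8, 6, 4, 2],
                [10, 12, 25, 30, 10, 8, 3, 2],
                [4, 6, 18, 34, 20, 12, 4, 2],
                [2, 0, 8, 14, 30, 28, 12, 6],
                [0, 0, 4, 8, 26, 34, 18, 10],
            ],
            dtype=np.int64,
        )
        return CountTable(samples, asvs, counts, kingdom=kingdom, days=days)

    def tree(prefix):
        a = [f"{prefix}{k + 1:04d}" for k in range(8)]
        nwk = (
            f"((({a[0]}:0.25,{a[1]}:0.25):0.25,({a[2]}:0.25,{a[3]}:0.25):0.25):0.5,"
            f"(({a[4]}:0.25,{a[5]}:0.25):0.25,({a[6]}:0.25,{a[7]}:0.25):0.25):0.5);"
        )
        return PhyloTree.from_newick(nwk)

    prok, euk = table("P", "prokaryote"), table("E", "eukaryote")
    stages = [assign_stage(d) for d in days]
    env = EnvTable(
        pd.DataFrame(
            {
                "day": days,
                "stage": stages,
                "latent_state": [0.0, 0.1, 0.9, 1.1, 1.9, 2.1],
                "nitrate": [2.0, 3.0, 13.0, 15.0, 25.0, 27.0],
                "vss": [1.5, 1.8, 4.2, 4.8, 7.2, 7.8],
                "phosphate": [30.0, 29.0, 22.0, 21.0, 14.0, 13.0],
                "toc": [18.0, 17.5, 15.0, 14.5, 12.0, 11.5],
            },
            index=samples,
        )
    )
    guild = np.array([1, 1, 2, 2, 3, 3, 3, 3])
    optimum = np.array([0.0, 0.1, 1.0, 1.1, 1.9, 2.0, 2.1, 2.2])
    frames = []
    for prefix, kingdom in (("P", "prokaryote"), ("E", "eukaryote")):
        frames.append(
            pd.DataFrame(
                {
                    "asv_id": [f"{prefix}{k + 1:04d}" for k in range(8)],
                    "kingdom": kingdom,
                    "guild": guild,
                    "optimum": optimum,
                    "trait": optimum,
                }
            )
        )
    truth = {
        "asv_truth": pd.concat(frames, ignore_index=True),
        "coupled_guilds": [],
        "stage_regime": {"floccular": "selection", "intermediate": "selection", "granular": "drift"},
        "scenario": None,
    }
    return SyntheticDataset(prok, euk, tree("P"), tree("E"), env, truth)
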