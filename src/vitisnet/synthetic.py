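"""Synthetic metabolite-profiling data with known ground truth.

The generator emulates a two-cultivar (Cs, Sh) x two-treatment (irrigated IR,
water deficit D) x four-day greenhouse design with six replicates per cell:

* intensities are log-normal — normal on the log10 scale with noise sigma
  (default 0.15), strictly positive on the intensity scale;
* metabolites come in compound-class blocks whose within-block correlation is
  induced by a single latent factor per class and sample: a member's log10
  value loads sqrt(rho) on the factor and sqrt(1-rho) on private noise, so
  the expected pairwise correlation inside a block is exactly rho. rho may
  differ per cultivar x treatment, which is how a condition acquires a denser
  correlation network;
* the water-deficit arm multiplies group means by per-metabolite,
  per-day effect trajectories (amino acids strongly up, most organic acids
  down), progressive across days;
* the first design day is pre-divergence: both arms are generated from the
  irrigated distribution with no treatment effect;
* physiological traits (leaf water potential Psi_l, osmolality pi, stomatal
  conductance g_s, ABA, net assimilation, C/N) are noisy linear functions of
  designated log10 metabolite columns (or of previously generated traits)
  hitting a target Pearson correlation in expectation.

Every effect size, correlation and coupling is returned in a ground-truth
record so downstream stages can be checked against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_profiles import ProfileMatrix

__all__ = [
    "ClassSpec",
    "TraitCoupling",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "preset_paper_like",
    "latent_block_matrix",
]


@dataclass
class ClassSpec:
    name: str
    platform: str               # "GC" or "LC"
    n_members: int
    mu: float                   # baseline log10 intensity of the class
    named: tuple = ()           # explicit member names; rest are auto-named


@dataclass
class TraitCoupling:
    trait: str
    source: str                 # metabolite id (log10 scale) or earlier trait
    r: float                    # signed target Pearson correlation
    loc: float = 0.0
    scale: float = 1.0
    clip_low: float | None = None
    clip_high: float | None = None


@dataclass
class SyntheticSpec:
    classes: list
    cultivars: tuple = ("Cs", "Sh")
    treatments: tuple = ("IR", "D")
    days: tuple = (4, 18, 26, 34)
    replicates: int = 6
    sigma: float = 0.15
    #: within-class latent-factor correlation per (cultivar, treatment)
    rho: dict = field(default_factory=dict)
    #: metabolite -> cultivar -> day-34 fold (ramped) or {day: fold}
    effects: dict = field(default_factory=dict)
    couplings: list = field(default_factory=list)
    #: (metabolite, cultivar, treatment) whose latent loading is cut and whose
    #: noise is widened under that condition (the "lost all relations" scenario)
    decoupled: dict = field(default_factory=dict)
    #: fraction of the day-34 log10 effect reached at each day
    ramp: dict = field(default_factory=lambda: {4: 0.0, 18: 0.4, 26: 0.75, 34: 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        for key, rho in self.rho.items():
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"rho must be in [0, 1), got {rho} for {key}")
        for coupling in self.couplings:
            if abs(coupling.r) >= 1.0:
                raise ValueError(f"infeasible coupling |r| >= 1 for {coupling.trait}")
        if self.replicates < 2:
            raise ValueError("need at least two replicates per design cell")

    def metabolites(self) -> list[tuple[str, str, str, float]]:
        """(metabolite_id, class, platform, mu) in deterministic order."""
        out = []
        for cls in self.classes:
            names = list(cls.named)
            for i in range(len(names), cls.n_members):
                names.append(f"{cls.name.replace(' ', '_')}_{i + 1:02d}")
            for name in names[: cls.n_members]:
                out.append((name, cls.name, cls.platform, cls.mu))
        ids = [m[0] for m in out]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite names across classes")
        return out

    def effect(self, metabolite: str, cultivar: str, day: int) -> float:
        """Planted D/IR fold for one metabolite, cultivar and day."""
        per_cultivar = self.effects.get(metabolite, {})
        spec = per_cultivar.get(cultivar, 1.0)
        if isinstance(spec, dict):
            return float(spec.get(day, 1.0))
        return float(spec) ** self.ramp.get(day, 1.0)

    def null_variant(self) -> "SyntheticSpec":
        """Same design with all effects at 1 and rho = 0: the global null."""
        rho = {key: 0.0 for key in self.rho} or {
            (cv, tr): 0.0 for cv in self.cultivars for tr in self.treatments
        }
        return replace(self, effects={}, rho=rho, decoupled={}, couplings=list(self.couplings))


@dataclass
class SyntheticDataset:
    profile: ProfileMatrix
    traits: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Draw one dataset (profile matrix + traits + annotations + truth)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mets = spec.metabolites()
    met_ids = [m[0] for m in mets]
    classes = {m[0]: m[1] for m in mets}
    platforms = pd.Series({m[0]: m[2] for m in mets})
    mu = np.array([m[3] for m in mets])
    # per-metabolite baseline offsets: stable individual abundances
    mu = mu + rng.normal(0.0, 0.3, size=len(mets))

    class_names = [c.name for c in spec.classes]
    class_index = {name: [i for i, m in enumerate(mets) if m[1] == name] for name in class_names}
    prediv = spec.days[0]

    rows, meta_rows, ids = [], [], []
    for cultivar in spec.cultivars:
        for treatment in spec.treatments:
            for day in spec.days:
                n = spec.replicates
                pre = day == prediv
                rho_key = (cultivar, "IR" if pre else treatment)
                rho = spec.rho.get(rho_key, 0.0)
                log_vals = np.tile(mu, (n, 1)).astype(float)
                if treatment == "D" and not pre:
                    for j, met in enumerate(met_ids):
                        eff = spec.effect(met, cultivar, day)
                        log_vals[:, j] += np.log10(eff)
                eps = rng.normal(size=(n, len(mets)))
                for name in class_names:
                    idx = class_index[name]
                    latent = rng.normal(size=n)
                    load = np.full(len(idx), np.sqrt(rho))
                    noise_mult = np.ones(len(idx))
                    if not pre:
                        for pos, j in enumerate(idx):
                            key = (met_ids[j], cultivar, treatment)
                            if key in spec.decoupled:
                                load[pos] = 0.0
                                noise_mult[pos] = spec.decoupled[key]
                    z = (
                        latent[:, None] * load[None, :]
                        + np.sqrt(1.0 - load[None, :] ** 2) * eps[:, idx] * noise_mult[None, :]
                    )
                    log_vals[:, idx] += spec.sigma * z
                rows.append(10.0 ** log_vals)
                for rep in range(1, n + 1):
                    ids.append(f"{cultivar}_{treatment}_d{day:02d}_r{rep}")
                    meta_rows.append(
                        dict(cultivar=cultivar, treatment=treatment, day=day, replicate=rep)
                    )
    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="sample_id"), columns=met_ids
    )
    samples = pd.DataFrame(meta_rows, index=values.index)
    profile = ProfileMatrix(values, samples, platforms)

    traits = pd.DataFrame(index=values.index)
    sources: dict[str, np.ndarray] = {}
    for coupling in spec.couplings:
        if coupling.source in traits.columns:
            z_src = _zscore(traits[coupling.source].to_numpy())
        elif coupling.source in values.columns:
            z_src = _zscore(np.log10(values[coupling.source].to_numpy()))
        else:
            raise ValueError(f"coupling source {coupling.source!r} not found")
        noise = rng.normal(size=len(z_src))
        z = coupling.r * z_src + np.sqrt(1.0 - coupling.r**2) * noise
        trait = coupling.loc + coupling.scale * z
        if coupling.clip_low is not None or coupling.clip_high is not None:
            trait = np.clip(trait, coupling.clip_low, coupling.clip_high)
        traits[coupling.trait] = trait
        sources[coupling.trait] = z_src

    annotations = pd.DataFrame(
        {
            "compound_class": [classes[m] for m in met_ids],
            "tier": ["primary" if platforms[m] == "GC" else "secondary" for m in met_ids],
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )

    truth = dict(
        seed=int(spec.seed if seed is None else seed),
        sigma=spec.sigma,
        rho={f"{cv}|{tr}": spec.rho.get((cv, tr), 0.0) for cv in spec.cultivars for tr in spec.treatments},
        effects={
            met: {cv: {day: spec.effect(met, cv, day) for day in spec.days} for cv in spec.cultivars}
            for met in spec.effects
        },
        couplings=[(c.trait, c.source, c.r) for c in spec.couplings],
        decoupled={f"{m}|{cv}|{tr}": mult for (m, cv, tr), mult in spec.decoupled.items()},
        classes=classes,
        prediv_day=int(prediv),
    )
    return SyntheticDataset(profile, traits, annotations, truth)


# -- the study-like preset --------------------------------------------------

_AMINO = ("Pro", "Val", "Leu", "Thr", "Trp", "Phe", "Glu", "Gly", "Ser",
          "Ala", "Ile", "Asp", "Asn", "Gln", "Lys")
_ORGANIC = ("glycerate", "galactonate", "nicotinate", "citrate", "malate",
            "succinate", "fumarate", "quinate", "threonate", "tartarate",
            "glutarate", "malonate", "2,4-dihydroxybenzoate", "gallate",
            "ascorbate", "shikimate", "benzoate", "oxalate")
_SUGARS = ("sucrose", "glucose", "fructose", "raffinose", "melibiose",
           "ribulose", "galactinol", "myo-inositol", "trehalose", "xylose",
           "arabinose", "rhamnose", "fucose", "maltose", "mannose", "ribose")
_OTHER_GC = ("ethanolamine", "putrescine", "glycerol", "urea")
_PHENYLPROP = ("ferulate", "trans-5-O-caffeoyl-D-quinate",
               "4-O-caffeoyl-D-quinate", "caffeoyl tartarate",
               "coumaroyl tartarate", "p-coumarate hexose", "hydroxybenzoate",
               "hydroxybenzoate hexoside", "dihydroxybenzoate hexoside")
_FLAVONOIDS = ("quercetin", "quercetin-3-O-galactoside",
               "quercetin-3-O-glucuronide", "rutin", "catechin", "epicatechin",
               "epigallocatechin", "procyanidin B3", "astilbin")


def preset_paper_like(pro_decoupled: bool = False, seed: int = 0) -> SyntheticSpec:
    """The study-like scenario: 69 GC + 27 LC leaf metabolites in compound-
    class blocks, 2 cultivars x 2 treatments x days (4, 18, 26, 34) x 6
    replicates, progressive water-deficit effects (Pro up 251-fold in the
    stressed Shiraz arm at day 34, most organic acids down), and a
    connectivity contrast rho(Sh, D) > rho(Sh, IR) > rho(Cs, D) ~ rho(Cs, IR)
    so the stressed-Shiraz network is the densest.

    ``pro_decoupled`` switches on the scenario in which Pro leaves its class
    block under stressed Shiraz (latent loading cut, private noise widened):
    the proline node then loses its relations in that network while still
    accumulating strongly.
    """
    classes = [
        ClassSpec("amino acid", "GC", 15, 3.0, _AMINO),
        ClassSpec("organic acid", "GC", 18, 3.2, _ORGANIC),
        ClassSpec("sugar", "GC", 16, 3.5, _SUGARS),
        ClassSpec("other", "GC", 20, 3.0, _OTHER_GC),
        ClassSpec("phenylpropanoid", "LC", 14, 2.8, _PHENYLPROP),
        ClassSpec("flavonoid", "LC", 13, 2.8, _FLAVONOIDS),
    ]
    effects: dict = {
        # amino acids: day-34 fold (Sh, Cs), ramped across days
        "Pro": {"Sh": 251.0, "Cs": 162.0},
        "Val": {"Sh": 33.0, "Cs": 26.0},
        "Leu": {"Sh": 43.0, "Cs": 22.0},
        "Thr": {"Sh": 12.0, "Cs": 13.0},
        "Trp": {"Sh": 17.0, "Cs": 9.0},
        "Phe": {"Sh": 52.0, "Cs": 21.0},
        "Glu": {"Sh": 1.5, "Cs": 0.5},
        # most organic acids fall; the two sharpest:
        "glycerate": {"Sh": 1.0 / 32.0, "Cs": 1.0 / 40.0},
        "galactonate": {"Sh": 1.0 / 27.0, "Cs": 1.0 / 11.0},
        # nicotinate rises at every time point (explicit trajectory)
        "nicotinate": {
            "Sh": {18: 1.44, 26: 2.2, 34: 2.2},
            "Cs": {18: 1.25, 26: 1.99, 34: 1.81},
        },
        "succinate": {
            "Sh": {18: 1 / 3, 26: 1 / 3, 34: 1.0},
            "Cs": {18: 1 / 3, 26: 1 / 3, 34: 1.0},
        },
        "malate": {"Sh": {26: 1.6}},
        "fumarate": {"Sh": 1.0, "Cs": 1.0},
        "galactinol": {"Sh": 5.0, "Cs": 3.0},
        "ethanolamine": {"Sh": 2.0},
        # flavanols fall under deficit in both cultivars
        "catechin": {"Sh": 0.6, "Cs": 0.6},
        "epicatechin": {"Sh": 0.6, "Cs": 0.6},
        "epigallocatechin": {"Sh": 0.6, "Cs": 0.6},
        "procyanidin B3": {"Sh": 0.6, "Cs": 0.6},
        "quercetin-3-O-galactoside": {"Sh": 1.4},
        "rutin": {"Sh": 1.9},
        # benzoate derivatives accumulate in stressed Shiraz sap/leaf
        "hydroxybenzoate": {"Sh": 1.8},
        "hydroxybenzoate hexoside": {"Sh": 1.8},
        "dihydroxybenzoate hexoside": {"Sh": 1.8},
    }
    # generic responses for unnamed members
    for name in _AMINO:
        effects.setdefault(name, {"Sh": 4.0, "Cs": 3.0})
    for i in range(len(_AMINO), 15):
        effects[f"amino_acid_{i + 1:02d}"] = {"Sh": 4.0, "Cs": 3.0}
    for name in _ORGANIC:
        effects.setdefault(name, {"Sh": 0.4, "Cs": 0.6})
    rho = {
        ("Sh", "D"): 0.95,
        ("Sh", "IR"): 0.90,
        ("Cs", "D"): 0.85,
        ("Cs", "IR"): 0.84,
    }
    couplings = [
        TraitCoupling("psi_l", "Pro", -0.978, loc=-1.35, scale=0.45, clip_high=-0.05),
        TraitCoupling("pi", "psi_l", -0.883, loc=480.0, scale=90.0, clip_low=150.0),
        TraitCoupling("gs", "psi_l", 0.90, loc=0.18, scale=0.08, clip_low=0.005),
        TraitCoupling("ABA", "gs", -0.916, loc=1000.0, scale=350.0, clip_low=1.0),
        TraitCoupling("A_N", "gs", 0.90, loc=10.0, scale=4.0),
        TraitCoupling("CN_ratio", "Pro", -0.80, loc=25.0, scale=5.0, clip_low=3.0),
    ]
    decoupled = {("Pro", "Sh", "D"): 8.0} if pro_decoupled else {}
    return SyntheticSpec(
        classes=classes,
        effects=effects,
        rho=rho,
        couplings=couplings,
        decoupled=decoupled,
        seed=seed,
    )


def latent_block_matrix(
    n_samples: int,
    block_sizes: list[int],
    rho: float | list[float],
    sigma: float = 0.15,
    mu: float = 3.0,
    seed: int | np.random.Generator | None = None,
    prefix: str = "M",
) -> ProfileMatrix:
    """One-condition profile matrix with latent-factor correlation blocks.

    Each block of ``block_sizes`` gets its own latent factor; member log10
    values load sqrt(rho_block) on it. rho may be a scalar or per-block list.
    Useful for isolating network construction and the permutation test from
    the full study design.
    """
    rng = np.random.default_rng(seed)
    rhos = [rho] * len(block_sizes) if np.isscalar(rho) else list(rho)
    if len(rhos) != len(block_sizes):
        raise ValueError("need one rho per block")
    cols, blocks = [], []
    m = 0
    for b, (size, r) in enumerate(zip(block_sizes, rhos)):
        if not (0.0 <= r < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {r}")
        latent = rng.normal(size=n_samples)
        eps = rng.normal(size=(n_samples, size))
        z = np.sqrt(r) * latent[:, None] + np.sqrt(1.0 - r) * eps
        blocks.append(10.0 ** (mu + sigma * z))
        cols.extend(f"{prefix}{m + i + 1:03d}" for i in range(size))
        m += size
    ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    values = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(ids, name="sample_id"), columns=cols
    )
    samples = pd.DataFrame(
        dict(cultivar="synthetic", treatment="IR", day=1,
             replicate=np.arange(1, n_samples + 1)),
        index=values.index,
    )
    return ProfileMatrix(values, samples, pd.Series("GC", index=values.columns))
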