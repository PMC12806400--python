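"""Synthetic fermentation datasets with planted structure.

Emulates a two-arm fermentation study (an uninoculated control arm ``CK``
and an inoculated arm ``Lpscw``) sampled at days 0/3/10/30/45 with three
replicates per time point.  Latent genus abundances follow smooth log-scale
succession curves (logistic up, logistic down, or a Gaussian bump over the
day index), are closed to proportions, and optionally resampled at a finite
multinomial depth.  The generator plants three kinds of recoverable
structure and records them in a :class:`GroundTruth` ledger:

* **producers** — taxa whose relative abundance linearly drives designated
  flavor compounds (ester + acid pairs, or pairs of free amino acids);
* **hubs** — taxa sharing a per-sample latent factor with >= 4 partner taxa,
  so their abundance profiles co-vary and they become strong network nodes;
* **major** — taxa whose mean latent relative abundance exceeds 0.1 %.

An optional switch shuffles the fungal sub-composition of every sample in
one arm, erasing deterministic fungal presence structure there; this gives
the Raup-Crick assembly analysis a planted between-arm contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (
    AbundanceTable,
    CompoundTable,
    ConfigError,
    DataValidationError,
    SampleMetadata,
)

DEFAULT_COMPOUNDS_PER_CLASS: dict[str, int] = {
    "ester": 4,
    "acid": 3,
    "alcohol": 3,
    "aldehyde": 2,
    "phenol": 2,
    "amino_acid": 6,
    "organic_acid": 2,
    "physicochemical": 3,
}

#: the three physicochemical observables always emitted
PHYSCHEM_NAMES = ("pH", "reducing_sugar", "lactic_acid")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic fermentation study.

    Defaults mirror the study design the screen targets: two arms, days
    0/3/10/30/45, three replicates, 20 bacterial and 10 fungal genera.
    ``effect_size`` is the linear slope from producer relative abundance to
    driven-compound concentration; ``noise_sd`` the Gaussian measurement
    noise on driven compounds; ``depth`` the multinomial sequencing depth
    (0 means noiseless latent proportions).
    """

    n_bacteria: int = 20
    n_fungi: int = 10
    n_compounds_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUNDS_PER_CLASS)
    )
    n_producers: int = 4
    n_hubs: int = 3
    days: tuple[int, ...] = (0, 3, 10, 30, 45)
    replicates: int = 3
    groups: tuple[str, ...] = ("CK", "Lpscw")
    effect_size: float = 5.0
    noise_sd: float = 0.05
    depth: int = 50_000
    seed: int = 0
    # secondary structure knobs; loadings/noise are sized so that planted
    # signal (producer drive, hub factors) dominates the shared succession
    # trend that all taxa experience
    partners_per_hub: int = 6
    replicate_log_sd: float = 0.8
    hub_log_sd: float = 0.25
    partner_log_sd: float = 0.7
    hub_factor_loading: float = 1.2
    hub_trend_damping: float = 0.3
    partner_trend_damping: float = 0.5
    partner_loading_range: tuple[float, float] = (0.9, 1.05)
    pair_factor_loading: float = 1.2
    producer_base_mean: float = 1.8
    producer_base_sd: float = 0.5
    hub_base_mean: float = 0.6
    hub_base_sd: float = 0.5
    partner_base_mean: float = 0.2
    partner_base_sd: float = 0.6
    inoculated_boost: float = 1.0
    compound_arm_sd: float = 2.0
    detection_limit: float = 1e-4
    shuffle_fungi_arm: str | None = None

    def __post_init__(self) -> None:
        n_taxa = self.n_bacteria + self.n_fungi
        if self.n_producers > n_taxa or self.n_hubs > n_taxa:
            raise ConfigError("n_producers and n_hubs must not exceed total taxa")
        if list(self.days) != sorted(self.days) or (self.days and self.days[0] != 0):
            raise ConfigError("days must be sorted ascending and start at 0")
        if self.effect_size <= 0 or self.noise_sd < 0:
            raise ConfigError("effect_size must be > 0 and noise_sd >= 0")
        if self.depth < 0 or self.replicates < 1:
            raise ConfigError("depth must be >= 0 and replicates >= 1")
        needed = self.n_producers + self.n_hubs * (1 + self.partners_per_hub)
        if needed > n_taxa:
            raise ConfigError(
                f"need {needed} role taxa (producers + hub cliques) "
                f"but only {n_taxa} taxa configured"
            )
        classes = self.n_compounds_per_class
        n_flavor = (self.n_producers + 1) // 2
        n_amino = self.n_producers // 2
        if classes.get("ester", 0) < n_flavor or (
            classes.get("acid", 0) + classes.get("organic_acid", 0) < n_flavor
        ):
            raise ConfigError("not enough ester/acid compounds for flavor producers")
        if classes.get("amino_acid", 0) < 2 * n_amino:
            raise ConfigError("not enough amino-acid compounds for amino producers")
        if self.shuffle_fungi_arm is not None and self.shuffle_fungi_arm not in self.groups:
            raise ConfigError(f"shuffle_fungi_arm {self.shuffle_fungi_arm!r} not a group")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    taxa: tuple[str, ...]
    producers: dict[str, set[str]]  # taxon -> driven compound names
    hubs: set[str]
    major: set[str]
    trajectories: dict[str, np.ndarray]  # taxon -> per-day latent mean proportion
    partners: dict[str, set[str]] = field(default_factory=dict)
    inoculated: set[str] = field(default_factory=set)


def _trajectory(kind: str, t: np.ndarray, amp: float, t0: float, width: float) -> np.ndarray:
    """Log-scale succession curve over normalized day index t in [0, 1]."""
    if kind == "up":
        return amp / (1.0 + np.exp(-8.0 * (t - t0)))
    if kind == "down":
        return amp * (1.0 - 1.0 / (1.0 + np.exp(-8.0 * (t - t0))))
    return amp * np.exp(-((t - t0) ** 2) / (2.0 * width**2))  # bump


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[AbundanceTable, CompoundTable, SampleMetadata, GroundTruth]:
    """Generate one two-arm fermentation dataset, deterministically per seed."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    # independent streams so changing one component leaves the others untouched
    rng_roles, rng_traj, rng_noise, rng_comp, rng_phys, rng_shuffle, rng_depth = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    taxa = [f"Bact_{i + 1:02d}" for i in range(cfg.n_bacteria)] + [
        f"Fung_{i + 1:02d}" for i in range(cfg.n_fungi)
    ]
    kingdom = pd.Series(
        ["bacteria"] * cfg.n_bacteria + ["fungi"] * cfg.n_fungi,
        index=taxa,
        name="kingdom",
    )
    n_taxa = len(taxa)

    # --- role assignment: producers, hubs, hub partners (disjoint) ---------
    order = rng_roles.permutation(n_taxa)
    producers_idx = order[: cfg.n_producers]
    pos = cfg.n_producers
    hubs_idx = order[pos : pos + cfg.n_hubs]
    pos += cfg.n_hubs
    partner_idx: dict[int, np.ndarray] = {}
    for h in hubs_idx:
        partner_idx[h] = order[pos : pos + cfg.partners_per_hub]
        pos += cfg.partners_per_hub
    role_taxa = set(producers_idx) | set(hubs_idx) | {
        p for ps in partner_idx.values() for p in ps
    }
    # leftover background taxa form weak pairwise metabolic partnerships, as
    # real fermentation networks carry many doubleton correlations
    leftovers = order[pos:]
    background_pairs = [
        (leftovers[2 * i], leftovers[2 * i + 1]) for i in range(len(leftovers) // 2)
    ]

    # --- latent trajectories ----------------------------------------------
    days = np.asarray(cfg.days)
    t = np.linspace(0.0, 1.0, len(days))  # day index, not calendar day
    base = rng_traj.normal(0.0, 1.2, size=n_taxa)
    # role taxa are boosted so they clear the major-group prefilter;
    # producers are abundant genera, as real flavor producers are, so the
    # compound drive stays well above the measurement noise floor
    # clique bases are drawn from moderate distributions: a partner that
    # dominated the composition would, through closure, cancel the factor
    # response of its clique mates
    all_partners = [p for ps in partner_idx.values() for p in ps]
    base[all_partners] = rng_traj.normal(
        cfg.partner_base_mean, cfg.partner_base_sd, size=len(all_partners)
    )
    base[hubs_idx] = rng_traj.normal(cfg.hub_base_mean, cfg.hub_base_sd, size=len(hubs_idx))
    base[producers_idx] = rng_traj.normal(
        cfg.producer_base_mean, cfg.producer_base_sd, size=len(producers_idx)
    )
    kinds = rng_traj.choice(["up", "down", "bump"], size=n_taxa)
    amps = rng_traj.uniform(0.4, 1.0, size=n_taxa)
    # clique taxa are persistent keystone-like populations: their
    # succession swing is damped so the shared factor, not a common trend,
    # produces their co-variation
    amps[hubs_idx] *= cfg.hub_trend_damping
    amps[all_partners] *= cfg.partner_trend_damping
    t0s = rng_traj.uniform(0.2, 0.8, size=n_taxa)
    widths = rng_traj.uniform(0.12, 0.3, size=n_taxa)
    traj = np.stack(
        [_trajectory(kinds[i], t, amps[i], t0s[i], widths[i]) for i in range(n_taxa)]
    )  # n_taxa x n_days

    # occupancy windows: background taxa are succession specialists that are
    # genuinely absent outside their activity phase (late colonizers, early
    # aerobes, mid-fermentation transients), giving the presence/absence
    # structure a Raup-Crick analysis reads; clique taxa and producers are
    # generalists, so no sample can lose every taxon of a kingdom
    n_days = len(cfg.days)
    window = np.ones((n_taxa, n_days), dtype=bool)
    for i in leftovers:
        if kinds[i] == "up":
            onset = int(rng_traj.integers(1, 4))  # miss the first 1-3 days
            window[i, :onset] = False
        elif kinds[i] == "down":
            offset = int(rng_traj.integers(1, 4))  # miss the last 1-3 days
            window[i, n_days - offset :] = False
        else:
            window[i] = np.abs(t - t0s[i]) <= 0.35
    # specialists are otherwise quiet: damping their in-window trend keeps
    # the screen from reading the occupancy step as a compound association
    amps[leftovers] *= 0.5

    # --- sample grid -------------------------------------------------------
    records = []
    for g in cfg.groups:
        for d in cfg.days:
            for r in range(1, cfg.replicates + 1):
                records.append((f"{g}_d{d:02d}_r{r}", g, d, r))
    meta_frame = pd.DataFrame(
        records, columns=["sample_id", "group", "day", "replicate"]
    ).set_index("sample_id")
    meta = SampleMetadata(meta_frame)
    samples = meta.samples
    n_samples = len(samples)
    day_pos = {d: i for i, d in enumerate(cfg.days)}

    # --- latent log abundances --------------------------------------------
    # clique members (hubs + partners) carry less idiosyncratic noise so the
    # shared factor, not a huge loading, produces their co-variation; this
    # keeps any single taxon from episodically dominating the composition
    log_a = np.empty((n_taxa, n_samples))
    noise_sd_taxon = np.full(n_taxa, cfg.replicate_log_sd)
    noise_sd_taxon[[p for ps in partner_idx.values() for p in ps]] = cfg.partner_log_sd
    noise_sd_taxon[hubs_idx] = cfg.hub_log_sd
    eps = rng_noise.normal(0.0, 1.0, size=(n_taxa, n_samples)) * noise_sd_taxon[:, None]
    # bounded factor keeps any hub from episodically dominating the
    # composition (closure would otherwise cancel the planted correlation)
    factors = rng_noise.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(cfg.n_hubs, n_samples))
    pair_factors = rng_noise.uniform(
        -np.sqrt(3.0), np.sqrt(3.0), size=(len(background_pairs), n_samples)
    )
    lo, hi = cfg.partner_loading_range
    partner_loadings = {
        h: rng_noise.uniform(lo, hi, size=len(ps)) for h, ps in partner_idx.items()
    }
    inoculated = set(producers_idx)  # the arm-2 inoculum is the producer set
    boosted_arm = cfg.groups[1] if len(cfg.groups) > 1 else None
    for s, sid in enumerate(samples):
        g = meta.frame.loc[sid, "group"]
        d = int(meta.frame.loc[sid, "day"])
        col = base + traj[:, day_pos[d]] + eps[:, s]
        for k, h in enumerate(hubs_idx):
            col[h] += cfg.hub_factor_loading * factors[k, s]
            col[partner_idx[h]] += partner_loadings[h] * factors[k, s]
        for k, (p1, p2) in enumerate(background_pairs):
            col[[p1, p2]] += cfg.pair_factor_loading * pair_factors[k, s]
        if boosted_arm is not None and g == boosted_arm and d > 0:
            col[list(inoculated)] += cfg.inoculated_boost
        col[~window[:, day_pos[d]]] = -np.inf  # outside occupancy window
        log_a[:, s] = col

    latent = np.exp(log_a)
    latent /= latent.sum(axis=0, keepdims=True)

    # arm-specific fungal shuffling: erases deterministic fungal structure
    if cfg.shuffle_fungi_arm is not None:
        fungi_rows = np.arange(cfg.n_bacteria, n_taxa)
        for s, sid in enumerate(samples):
            if meta.frame.loc[sid, "group"] == cfg.shuffle_fungi_arm:
                perm = rng_shuffle.permutation(len(fungi_rows))
                latent[fungi_rows, s] = latent[fungi_rows[perm], s]

    # detection limit: genera below it are absent, as at finite read depth
    latent[latent < cfg.detection_limit] = 0.0
    colsum = latent.sum(axis=0, keepdims=True)
    if (colsum <= 0).any():
        raise DataValidationError("detection limit removed an entire sample")
    latent /= colsum

    if cfg.depth > 0:
        observed = np.empty_like(latent)
        for s in range(n_samples):
            counts = rng_depth.multinomial(cfg.depth, latent[:, s])
            observed[:, s] = counts / cfg.depth
    else:
        observed = latent.copy()

    abund = AbundanceTable(pd.DataFrame(observed, index=taxa, columns=samples), kingdom)

    # --- compounds ---------------------------------------------------------
    classes = cfg.n_compounds_per_class
    comp_names: list[str] = []
    comp_class: list[str] = []
    for cls, n in classes.items():
        if cls == "physicochemical":
            continue
        for i in range(n):
            comp_names.append(f"{cls}_{i + 1:02d}")
            comp_class.append(cls)
    comp_names.extend(PHYSCHEM_NAMES)
    comp_class.extend(["physicochemical"] * len(PHYSCHEM_NAMES))

    # assign driven compounds: odd producers get (ester, acid) pairs, even
    # producers get pairs of free amino acids
    producers: dict[str, set[str]] = {}
    acid_pool = [c for c, k in zip(comp_names, comp_class) if k in ("acid", "organic_acid")]
    ester_pool = [c for c, k in zip(comp_names, comp_class) if k == "ester"]
    amino_pool = [c for c, k in zip(comp_names, comp_class) if k == "amino_acid"]
    e_i = a_i = aa_i = 0
    for j, p in enumerate(producers_idx):
        name = taxa[p]
        if j % 2 == 0:
            producers[name] = {ester_pool[e_i], acid_pool[a_i]}
            e_i += 1
            a_i += 1
        else:
            producers[name] = {amino_pool[aa_i], amino_pool[aa_i + 1]}
            aa_i += 2

    driven = {c for cs in producers.values() for c in cs}
    conc = np.empty((len(comp_names), n_samples))
    taxon_row = {name: i for i, name in enumerate(taxa)}
    day_of_sample = meta.frame["day"].to_numpy()
    # flavor profiles of the two arms diverge as fermentation progresses:
    # each non-physicochemical compound gets an arm offset that ramps up
    # with day in the inoculated arm
    max_day = max(int(day_of_sample.max()), 1)
    in_boosted = (
        (meta.frame["group"] == boosted_arm).to_numpy()
        if boosted_arm is not None
        else np.zeros(n_samples, dtype=bool)
    )
    arm_ramp = in_boosted * (day_of_sample / max_day)
    for i, (cname, ccls) in enumerate(zip(comp_names, comp_class)):
        if cname in PHYSCHEM_NAMES:
            if cname == "pH":
                mean = 6.5 - 2.5 * (1.0 - np.exp(-day_of_sample / 10.0))
                noise = rng_phys.normal(0.0, 0.03, size=n_samples)
            elif cname == "reducing_sugar":
                mean = 8.0 * np.exp(-day_of_sample / 15.0)
                noise = rng_phys.normal(0.0, 0.05, size=n_samples)
            else:  # lactic_acid: rise then plateau
                mean = 3.0 * day_of_sample / (day_of_sample + 5.0)
                noise = rng_phys.normal(0.0, 0.05, size=n_samples)
            conc[i] = np.maximum(mean + noise, 0.0)
        elif cname in driven:
            producer = next(p for p, cs in producers.items() if cname in cs)
            drive = cfg.effect_size * latent[taxon_row[producer]]
            conc[i] = np.maximum(drive + rng_comp.normal(0.0, cfg.noise_sd, n_samples), 0.0)
        else:
            # background compound: smooth random trend, independent of taxa
            kind = rng_comp.choice(["up", "down", "bump"])
            amp = rng_comp.uniform(0.5, 2.0)
            t0 = rng_comp.uniform(0.2, 0.8)
            trend = _trajectory(kind, t, amp, t0, 0.2)
            arm_effect = rng_comp.normal(0.0, cfg.compound_arm_sd)
            mean = trend[[day_pos[d] for d in day_of_sample]] + arm_effect * arm_ramp
            conc[i] = np.maximum(
                0.5 + mean + rng_comp.normal(0.0, 0.3, n_samples), 0.0
            )

    comp = CompoundTable(
        pd.DataFrame(conc, index=comp_names, columns=samples),
        pd.Series(comp_class, index=comp_names, name="compound_class"),
    )

    # --- ground truth ------------------------------------------------------
    mean_by_day = {
        taxa[i]: np.array(
            [
                latent[i, [s for s, d in enumerate(day_of_sample) if d == day]].mean()
                for day in cfg.days
            ]
        )
        for i in range(n_taxa)
    }
    major = {taxa[i] for i in range(n_taxa) if latent[i].mean() > 0.001}
    truth = GroundTruth(
        taxa=tuple(taxa),
        producers=producers,
        hubs={taxa[h] for h in hubs_idx},
        major=major,
        trajectories=mean_by_day,
        partners={taxa[h]: {taxa[p] for p in ps} for h, ps in partner_idx.items()},
        inoculated={taxa[i] for i in inoculated},
    )
    return abund, comp, meta, truth


def precision_recall(found: set[str], planted: set[str]) -> dict[str, float | None]:
    """Set-overlap precision/recall; precision is None (NA) when nothing found."""
    tp = len(found & planted)
    precision = tp / len(found) if found else (1.0 if not planted else None)
    recall = tp / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall}


def expected_recovery(truth: GroundTruth, groups) -> dict[str, dict[str, float | None]]:
    """Score each screened group against the generator's ledger.

    ``groups`` is a :class:`~syncomscreen.selection.FunctionalGroups`.  The
    producer set is compared against flavor + amino-acid members jointly,
    hubs against the co-occurring group, and major taxa against the major
    group.  Any screened taxon outside the ledger's universe is a fatal
    name mismatch.
    """
    universe = set(truth.taxa)
    planted_producers = set(truth.producers)
    report: dict[str, dict[str, float | None]] = {}
    for name, found, planted in [
        ("producers", groups.flavor | groups.amino_acid, planted_producers),
        ("hubs", groups.cooccurring, truth.hubs),
        ("major", groups.major, truth.major),
    ]:
        stray = found - universe
        if stray:
            raise DataValidationError(
                f"screened taxa absent from ground-truth universe: {sorted(stray)}"
            )
        report[name] = precision_recall(found, planted)
    return report
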