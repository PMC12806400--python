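"""End-to-end screening pipeline.

Runs load (or simulate) -> normalize -> associations -> group assignment ->
co-occurrence network -> hubs -> cross-reference -> culturability
substitution -> diversity/distances -> Mantel + ANOSIM -> Raup-Crick ->
NMDS -> assembly summary, writing every module's output plus a
``manifest.json`` that records each default standing in for a parameter the
source study leaves unstated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .assembly import assembly_summary, nmds, raup_crick
from .association import (
    alpha_diversity,
    anosim,
    assign_amino_acid_group,
    assign_flavor_group,
    assign_major_group,
    compound_distance_matrix,
    distance_matrix,
    mantel_test,
    pairwise_association,
)
from .cooccurrence import build_network, hub_taxa
from .selection import (
    DEFAULT_RULE,
    cross_reference,
    make_functional_groups,
    substitute_members,
    syncom_report,
)
from .synthetic_community import GeneratorConfig, expected_recovery, generate_dataset
from .tables_io import (
    ConfigError,
    load_dataset,
    to_relative_abundance,
    write_abundance,
    write_compounds,
    write_manifest,
    write_metadata,
)

log = logging.getLogger("syncomscreen")

#: every file a successful screen run writes into its results directory
RESULT_FILES = (
    "associations.tsv",
    "groups.tsv",
    "network_edges.tsv",
    "network.graphml",
    "syncom.tsv",
    "alpha_diversity.tsv",
    "stats.json",
    "rc_matrix.tsv",
    "nmds_coords.tsv",
    "assembly_summary.tsv",
    "manifest.json",
)

#: screen/assembly defaults; True marks values the source study never states
SCREEN_DEFAULTS: dict[str, tuple[object, bool]] = {
    "method": ("spearman", True),
    "alpha": (0.05, False),
    "rho_min": (0.6, True),
    "min_hits": (2, True),
    "major_threshold": (0.001, False),
    "hub_quantile": (0.8, True),
    "bh_family": ("per_compound_class", True),
    "correlation_unit": ("per_sample", True),
    "rule": (DEFAULT_RULE, True),
    "rc_reps": (999, True),
    "nmds_k": (2, False),
    "nmds_restarts": (10, True),
    "mantel_permutations": (999, True),
    "anosim_permutations": (999, True),
}


class StageError(RuntimeError):
    """Wraps a module failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    import tomllib

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _screen_params(config: dict) -> dict:
    params = {name: default for name, (default, _) in SCREEN_DEFAULTS.items()}
    overrides = config.get("screen", {}) | config.get("assembly", {})
    unknown = set(overrides) - set(params) - {"per_group", "culturable"}
    if unknown:
        raise ConfigError(f"unknown screen/assembly option(s): {sorted(unknown)}")
    params.update({k: v for k, v in overrides.items() if k in params})
    return params


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    return {
        "mantel": int(state[0]),
        "anosim": int(state[1]),
        "raup_crick": int(state[2]),
        "nmds": int(state[3]),
    }


def run_screen(config: dict, out_dir: str | Path, keep_partial: bool = False) -> Path:
    """Execute the full screen; returns the results directory.

    ``config`` needs either a ``[simulate]`` block (generator parameters)
    or an ``[inputs]`` block with ``abundance``/``compounds``/``metadata``
    paths, plus an integer top-level ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_screen(config, out)
    except Exception:
        if not keep_partial:
            for name in RESULT_FILES:
                (out / name).unlink(missing_ok=True)
        raise


def _run_screen(config: dict, out: Path) -> Path:
    seed = config.get("seed")
    if not isinstance(seed, int):
        raise ConfigError("config requires an integer top-level 'seed'")
    params = _screen_params(config)
    seeds = _stage_seeds(seed)
    step = 0

    def stage(name: str):
        nonlocal step
        step += 1
        log.info("stage=%s step=%d seed=%d", name, step, seed)
        return name

    truth = None
    current = stage("load")
    try:
        if "simulate" in config:
            gen_cfg = GeneratorConfig(**config["simulate"], seed=seed)
            abund, comp, meta, truth = generate_dataset(gen_cfg)
            write_abundance(abund, out / "abundance.tsv")
            write_compounds(comp, out / "compounds.tsv")
            write_metadata(meta, out / "metadata.tsv")
        elif "inputs" in config:
            inputs = config["inputs"]
            for key in ("abundance", "compounds", "metadata"):
                if key not in inputs:
                    raise ConfigError(f"[inputs] block missing {key!r} path")
            abund, comp, meta = load_dataset(
                inputs["abundance"], inputs["compounds"], inputs["metadata"]
            )
        else:
            raise ConfigError("config requires a [simulate] or [inputs] block")

        current = stage("normalize")
        abund = to_relative_abundance(abund)

        current = stage("associations")
        assoc = pairwise_association(abund, comp, method=params["method"])
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)

        current = stage("groups")
        flavor = assign_flavor_group(assoc, alpha=params["alpha"], rho_min=params["rho_min"])
        amino = assign_amino_acid_group(
            assoc,
            alpha=params["alpha"],
            rho_min=params["rho_min"],
            min_hits=params["min_hits"],
        )
        major = assign_major_group(abund, threshold=params["major_threshold"])

        current = stage("network")
        net = build_network(
            abund,
            method=params["method"],
            rho_min=params["rho_min"],
            alpha=params["alpha"],
            taxa=major or None,
        )
        net.write_edges(out / "network_edges.tsv")
        net.write_graphml(out / "network.graphml")

        current = stage("hubs")
        hubs = hub_taxa(net, quantile=params["hub_quantile"])
        groups = make_functional_groups(
            flavor,
            amino,
            hubs,
            major,
            associations=assoc,
            strengths=net.strengths,
            mean_abundance=abund.data.mean(axis=1),
            rho_min=params["rho_min"],
            alpha=params["alpha"],
        )
        groups.membership_frame().to_csv(out / "groups.tsv", sep="\t", index=False)

        current = stage("cross_reference")
        candidates = cross_reference(groups, rule=params["rule"])

        current = stage("substitution")
        culturable_cfg = config.get("screen", {}).get("culturable")
        culturable = set(culturable_cfg) if culturable_cfg is not None else set(candidates)
        final, sub_log = substitute_members(candidates, culturable, groups)
        syncom_report(final, groups, sub_log).to_csv(out / "syncom.tsv", sep="\t", index=False)

        current = stage("diversity")
        alpha_diversity(abund).to_csv(out / "alpha_diversity.tsv", sep="\t")

        current = stage("distances")
        bact = abund.subset_kingdom("bacteria")
        fung = abund.subset_kingdom("fungi")
        d_bact = distance_matrix(to_relative_abundance(bact), "bray_curtis")
        d_fung = distance_matrix(to_relative_abundance(fung), "bray_curtis")
        d_comp = compound_distance_matrix(comp)

        current = stage("mantel_anosim")
        stats_out: dict[str, dict] = {"seed": seeds}
        r_b, p_b = mantel_test(
            d_comp, d_bact, method=params["method"],
            permutations=params["mantel_permutations"], seed=seeds["mantel"],
        )
        r_f, p_f = mantel_test(
            d_comp, d_fung, method=params["method"],
            permutations=params["mantel_permutations"], seed=seeds["mantel"],
        )
        labels = meta.frame.loc[d_comp.labels, "group"].to_numpy()
        r_an, p_an = anosim(
            d_comp, labels, permutations=params["anosim_permutations"], seed=seeds["anosim"]
        )
        stats_out.update(
            {
                "mantel_bacteria_vs_compounds": {"r": r_b, "p": p_b},
                "mantel_fungi_vs_compounds": {"r": r_f, "p": p_f},
                "anosim_compounds_by_group": {"R": r_an, "p": p_an},
            }
        )

        current = stage("raup_crick")
        rc = raup_crick(abund, reps=params["rc_reps"], seed=seeds["raup_crick"])
        rc.write(out / "rc_matrix.tsv")

        current = stage("nmds")
        ord_res = nmds(rc, k=params["nmds_k"], restarts=params["nmds_restarts"],
                       seed=seeds["nmds"])
        ord_res.write(out / "nmds_coords.tsv")
        stats_out["nmds"] = {"stress": ord_res.stress, "converged": ord_res.converged}

        current = stage("summary")
        assembly_summary(rc, meta).to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
        if truth is not None:
            stats_out["recovery"] = expected_recovery(truth, groups)
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "producers": {k: sorted(v) for k, v in truth.producers.items()},
                        "hubs": sorted(truth.hubs),
                        "major": sorted(truth.major),
                        "inoculated": sorted(truth.inoculated),
                    },
                    indent=2,
                )
            )
        (out / "stats.json").write_text(json.dumps(stats_out, indent=2, default=float))

        current = stage("manifest")
        manifest = {
            "version": __version__,
            "seed": seed,
            "stage_seeds": seeds,
            "parameters": {
                name: {"value": params[name], "paper_unstated": unstated}
                for name, (_, unstated) in SCREEN_DEFAULTS.items()
            },
            "syncom": sorted(final),
            "candidates": sorted(candidates),
        }
        if "simulate" in config:
            manifest["simulate"] = asdict(gen_cfg)
        write_manifest(manifest, out / "manifest.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(current, exc) from exc
    return out


def run_simulate(config: dict, out_dir: str | Path) -> Path:
    """Generate one synthetic dataset and write its TSVs + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("'seed' must be an integer")
    gen_cfg = GeneratorConfig(**config.get("simulate", {}), seed=seed)
    abund, comp, meta, truth = generate_dataset(gen_cfg)
    write_abundance(abund, out / "abundance.tsv")
    write_compounds(comp, out / "compounds.tsv")
    write_metadata(meta, out / "metadata.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "producers": {k: sorted(v) for k, v in truth.producers.items()},
                "hubs": sorted(truth.hubs),
                "major": sorted(truth.major),
                "inoculated": sorted(truth.inoculated),
                "config": asdict(gen_cfg),
            },
            indent=2,
        )
    )
    return out


def run_assembly(
    abundance_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    per_group: bool = True,
    reps: int = 999,
    seed: int = 0,
) -> Path:
    """Raup-Crick + NMDS on an existing dataset, by default per study arm."""
    from .tables_io import read_abundance, read_metadata, _check_sample_universe

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    abund = read_abundance(abundance_path)
    meta = read_metadata(metadata_path)
    _check_sample_universe("abundance", abund.samples, meta)
    abund = to_relative_abundance(abund.subset_samples(meta.samples))

    scopes: list[tuple[str, list[str]]]
    if per_group:
        scopes = [
            (str(g), list(sub.index)) for g, sub in meta.frame.groupby("group", sort=True)
        ]
    else:
        scopes = [("all", meta.samples)]
    for name, samples in scopes:
        sub = abund.subset_samples(samples)
        rc = raup_crick(sub, reps=reps, seed=seed)
        rc.write(out / f"rc_matrix_{name}.tsv")
        ord_res = nmds(rc, seed=seed)
        ord_res.write(out / f"nmds_coords_{name}.tsv")
        summary = assembly_summary(rc, meta)
        summary.to_csv(out / f"assembly_summary_{name}.tsv", sep="\t", index=False)
    return out
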