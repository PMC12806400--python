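"""Cross-referencing functional groups into SynCom candidates.

The four screened groups (flavor, amino_acid, cooccurring, major) are
combined by a small user-configurable set expression — default
``(flavor | amino_acid) & cooccurring & major`` — into the SynCom candidate
set.  A final culturability step replaces each candidate that could not be
isolated with the best-supported culturable taxon sharing a functional
group with it (the field precedent: an abundant but unculturable
amino-acid-producing yeast is stood in for by a culturable *Saccharomyces*).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .tables_io import ACID_CLASSES, ConfigError, DataValidationError

DEFAULT_RULE = "(flavor | amino_acid) & cooccurring & major"

GROUP_NAMES = ("flavor", "amino_acid", "cooccurring", "major")


@dataclass
class FunctionalGroups:
    """Named taxon sets produced by the screen, plus per-taxon evidence.

    ``provenance`` maps each taxon to a list of (group, supporting
    statistic): the best qualifying correlation for flavor/amino_acid,
    network strength for cooccurring, mean relative abundance for major.
    """

    flavor: set[str] = field(default_factory=set)
    amino_acid: set[str] = field(default_factory=set)
    cooccurring: set[str] = field(default_factory=set)
    major: set[str] = field(default_factory=set)
    syncom: set[str] = field(default_factory=set)
    provenance: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, set[str]]:
        return {name: getattr(self, name) for name in GROUP_NAMES}

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for group in GROUP_NAMES:
            for taxon in sorted(getattr(self, group)):
                stat = dict(self.provenance.get(taxon, [])).get(group)
                rows.append((taxon, group, stat))
        return pd.DataFrame(rows, columns=["taxon", "group", "evidence"])


def make_functional_groups(
    flavor: set[str],
    amino_acid: set[str],
    cooccurring: set[str],
    major: set[str],
    associations: pd.DataFrame | None = None,
    strengths: pd.Series | None = None,
    mean_abundance: pd.Series | None = None,
    rho_min: float = 0.6,
    alpha: float = 0.05,
) -> FunctionalGroups:
    """Assemble a FunctionalGroups with per-taxon supporting statistics."""
    groups = FunctionalGroups(
        flavor=set(flavor),
        amino_acid=set(amino_acid),
        cooccurring=set(cooccurring),
        major=set(major),
    )
    prov: dict[str, list[tuple[str, float]]] = {}

    def add(taxon: str, group: str, stat: float) -> None:
        prov.setdefault(taxon, []).append((group, float(stat)))

    if associations is not None:
        ok = (
            (associations["rho"] >= rho_min)
            & (associations["q"] < alpha)
            & ~associations["degenerate"]
        )
        hits = associations[ok]
        flavor_classes = {"ester"} | set(ACID_CLASSES)
        for taxon in groups.flavor:
            sub = hits[(hits["taxon"] == taxon) & hits["compound_class"].isin(flavor_classes)]
            if len(sub):
                add(taxon, "flavor", sub["rho"].max())
        for taxon in groups.amino_acid:
            sub = hits[(hits["taxon"] == taxon) & (hits["compound_class"] == "amino_acid")]
            if len(sub):
                add(taxon, "amino_acid", sub["rho"].max())
    if strengths is not None:
        for taxon in groups.cooccurring:
            if taxon in strengths.index:
                add(taxon, "cooccurring", strengths[taxon])
    if mean_abundance is not None:
        for taxon in groups.major:
            if taxon in mean_abundance.index:
                add(taxon, "major", mean_abundance[taxon])
    groups.provenance = prov
    return groups


# --- tiny set-expression parser: names, |, &, parentheses ------------------

_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|[|&()])")


def _tokenize(rule: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if not m:
            if rule[pos:].strip():
                raise ConfigError(f"bad character in rule at {rule[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def evaluate_rule(rule: str, sets: dict[str, set[str]]) -> set[str]:
    """Evaluate a union/intersection expression over named taxon sets.

    ``&`` binds tighter than ``|``; parentheses group.  Unknown group names
    are fatal.
    """
    tokens = _tokenize(rule)
    if not tokens:
        raise ConfigError("empty cross-reference rule")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def atom() -> set[str]:
        tok = peek()
        if tok == "(":
            take()
            value = union()
            if peek() != ")":
                raise ConfigError(f"unbalanced parentheses in rule {rule!r}")
            take()
            return value
        if tok is None or tok in "|&)":
            raise ConfigError(f"expected group name in rule {rule!r}")
        take()
        if tok not in sets:
            raise ConfigError(
                f"unknown group {tok!r} in rule; known groups: {sorted(sets)}"
            )
        return set(sets[tok])

    def intersection() -> set[str]:
        value = atom()
        while peek() == "&":
            take()
            value = value & atom()
        return value

    def union() -> set[str]:
        value = intersection()
        while peek() == "|":
            take()
            value = value | intersection()
        return value

    result = union()
    if pos != len(tokens):
        raise ConfigError(f"trailing tokens in rule {rule!r}")
    return result


def cross_reference(
    groups: FunctionalGroups,
    rule: str = DEFAULT_RULE,
    min_size: int = 2,
) -> set[str]:
    """Evaluate the cross-referencing rule into the SynCom candidate set."""
    candidates = evaluate_rule(rule, groups.as_dict())
    if len(candidates) < min_size:
        warnings.warn(
            f"cross-reference produced only {len(candidates)} candidate(s) "
            f"(min_size={min_size})",
            stacklevel=2,
        )
    groups.syncom = set(candidates)
    return set(candidates)


def _evidence(taxon: str, shared: list[str], groups: FunctionalGroups) -> float:
    """Best supporting statistic of ``taxon`` across the shared groups.

    Correlation-backed groups (flavor, amino_acid) are preferred; network
    strength / abundance statistics are only used when no correlation
    evidence exists, scaled into a secondary band so a correlation always
    outranks them.
    """
    prov = dict(groups.provenance.get(taxon, []))
    corr = [prov[g] for g in shared if g in ("flavor", "amino_acid") and g in prov]
    if corr:
        return max(corr)
    other = [prov[g] for g in shared if g in prov]
    return max(other) / 1e6 if other else 0.0


def substitute_members(
    candidates: set[str],
    culturable: set[str],
    groups: FunctionalGroups,
) -> tuple[set[str], list[dict]]:
    """Replace unculturable candidates with functionally matched isolates.

    Each unculturable candidate is swapped for the highest-evidence
    culturable taxon (not already a candidate) that shares at least one
    functional group with it; candidates with no eligible stand-in are
    dropped.  Every decision is logged; no outcome is an error.
    """
    final: set[str] = set()
    log: list[dict] = []
    membership = groups.as_dict()
    for cand in sorted(candidates):
        if cand in culturable:
            final.add(cand)
            log.append({"candidate": cand, "action": "kept", "substitute": None})
            continue
        cand_groups = [g for g, members in membership.items() if cand in members]
        best, best_ev, best_shared = None, -1.0, None
        for alt in sorted(culturable - candidates):
            shared = [g for g in cand_groups if alt in membership[g]]
            if not shared:
                continue
            ev = _evidence(alt, shared, groups)
            if ev > best_ev:
                best, best_ev, best_shared = alt, ev, shared
        if best is None:
            log.append(
                {
                    "candidate": cand,
                    "action": "dropped",
                    "substitute": None,
                    "reason": "no culturable taxon shares a functional group",
                }
            )
        else:
            final.add(best)
            log.append(
                {
                    "candidate": cand,
                    "action": "substituted",
                    "substitute": best,
                    "shared_groups": best_shared,
                    "evidence": best_ev,
                }
            )
    return final, log


def syncom_report(
    final: set[str],
    groups: FunctionalGroups,
    log: list[dict],
) -> pd.DataFrame:
    """One row per final SynCom member with sources, evidence, and notes."""
    notes = {}
    for rec in log:
        if rec["action"] == "substituted":
            notes[rec["substitute"]] = f"substitute for {rec['candidate']}"
        elif rec["action"] == "kept":
            notes[rec["candidate"]] = "screened candidate (culturable)"
    rows = []
    membership = groups.as_dict()
    for taxon in sorted(final):
        source = [g for g, members in membership.items() if taxon in members]
        prov = dict(groups.provenance.get(taxon, []))
        evidence = "; ".join(f"{g}={prov[g]:.3g}" for g in source if g in prov)
        rows.append((taxon, ",".join(source), evidence, notes.get(taxon, "")))
    return pd.DataFrame(rows, columns=["member", "source_groups", "evidence", "note"])
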