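"""Declarative genotype -> growth prediction rules.

Rules are data, not code: a YAML/JSON config lists species-scoped rules,
each with a boolean predicate over gene presence, locus states,
functionality flags, FL-transporter clades and GH families, a predicted
outcome (growth / no_growth) and a priority. For every (species,
substrate) the satisfied rule with the highest priority wins; two
satisfied rules of equal priority with conflicting predictions are a
configuration error. The shipped default distils the species-specific
utilization narratives for the six HMOs (see data/default_rules.yaml for
the rule-by-rule rationale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .catalog import Catalog, GH_FAMILIES, FL_CLADES
from .loci import StrainGenotype

SUBSTRATES = ("LNT", "LNnT", "FL2p", "FL3", "SL3p", "SL6p")
ALL_SUBSTRATES = SUBSTRATES + (
    "lactose", "glucose", "galactose", "fucose", "GlcNAc", "Neu5Ac",
)
PREDICTIONS = ("growth", "no_growth")


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class Rule:
    name: str
    species: str  # species name or "any"
    substrate: str
    predicate: Mapping
    prediction: str
    priority: int


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]

    def applicable(self, species: str, substrate: str) -> list[Rule]:
        return sorted(
            (
                r for r in self.rules
                if r.substrate == substrate
                and r.species in (species, "any")
            ),
            key=lambda r: (-r.priority, r.name),
        )


@dataclass(frozen=True)
class PredictionRecord:
    strain_id: str
    substrate: str
    predicted: str
    rule_name: str
    rule_trace: tuple[str, ...]


def _validate_predicate(pred: Mapping, catalog: Catalog, rule_name: str) -> None:
    if not isinstance(pred, Mapping) or len(pred) != 1:
        raise RuleError(f"rule {rule_name}: malformed predicate {pred!r}")
    op, arg = next(iter(pred.items()))
    if op in ("all", "any"):
        if not isinstance(arg, Sequence) or not arg:
            raise RuleError(f"rule {rule_name}: {op} needs a nonempty list")
        for sub in arg:
            _validate_predicate(sub, catalog, rule_name)
    elif op == "not":
        _validate_predicate(arg, catalog, rule_name)
    elif op == "gene":
        if arg not in catalog.genes:
            raise RuleError(f"rule {rule_name}: unknown gene {arg!r}")
    elif op == "locus_state":
        locus, state = arg
        if locus not in catalog.loci:
            raise RuleError(f"rule {rule_name}: unknown locus {locus!r}")
        if state not in ("complete", "partial", "absent"):
            raise RuleError(f"rule {rule_name}: unknown state {state!r}")
    elif op == "functional":
        if arg not in catalog.loci:
            raise RuleError(f"rule {rule_name}: unknown locus {arg!r}")
    elif op == "clade":
        gene, label = arg
        if gene not in catalog.genes:
            raise RuleError(f"rule {rule_name}: unknown gene {gene!r}")
        if label not in FL_CLADES:
            raise RuleError(f"rule {rule_name}: unknown clade {label!r}")
    elif op == "family":
        if arg not in GH_FAMILIES:
            raise RuleError(f"rule {rule_name}: unknown GH family {arg!r}")
    elif op == "always":
        if arg is not True:
            raise RuleError(f"rule {rule_name}: 'always' only takes true")
    else:
        raise RuleError(f"rule {rule_name}: unknown predicate op {op!r}")


def evaluate_predicate(
    pred: Mapping, genotype: StrainGenotype, catalog: Catalog
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate a predicate; returns (satisfied, satisfied leaf atoms)."""
    op, arg = next(iter(pred.items()))
    if op == "all":
        traces: list[str] = []
        for sub in arg:
            ok, tr = evaluate_predicate(sub, genotype, catalog)
            if not ok:
                return False, ()
            traces.extend(tr)
        return True, tuple(traces)
    if op == "any":
        for sub in arg:
            ok, tr = evaluate_predicate(sub, genotype, catalog)
            if ok:
                return True, tr
        return False, ()
    if op == "not":
        ok, _ = evaluate_predicate(arg, genotype, catalog)
        return (not ok), (f"not({_atom_str(arg)})",) if not ok else ()
    if op == "gene":
        ok = genotype.gene_present(arg)
        return ok, (f"gene({arg})",) if ok else ()
    if op == "locus_state":
        locus, state = arg
        call = genotype.locus_calls.get(locus)
        if call is None:
            raise RuleError(
                f"genotype {genotype.strain_id}: missing locus call "
                f"{locus!r}"
            )
        ok = call.state == state
        return ok, (f"locus_state({locus},{state})",) if ok else ()
    if op == "functional":
        call = genotype.locus_calls.get(arg)
        if call is None:
            raise RuleError(
                f"genotype {genotype.strain_id}: missing locus call {arg!r}"
            )
        return call.functional, (f"functional({arg})",) if call.functional else ()
    if op == "clade":
        gene, label = arg
        ok = (
            genotype.gene_present(gene)
            and catalog.genes[gene].fl_clade == label
        )
        return ok, (f"clade({gene},{label})",) if ok else ()
    if op == "family":
        ok = any(
            genotype.gene_present(g) for g in catalog.genes_in_family(arg)
        )
        return ok, (f"family({arg})",) if ok else ()
    if op == "always":
        return True, ("always",)
    raise RuleError(f"unknown predicate op {op!r}")


def _atom_str(pred: Mapping) -> str:
    op, arg = next(iter(pred.items()))
    return f"{op}({arg})"


def load_rules(path: str | Path, catalog: Catalog) -> RuleSet:
    """Load and validate a rule config against a catalog."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_rules(raw, catalog)


def parse_rules(raw: Mapping, catalog: Catalog) -> RuleSet:
    rules: list[Rule] = []
    for entry in raw.get("rules", []):
        rule = Rule(
            name=entry["name"],
            species=entry.get("species", "any"),
            substrate=entry["substrate"],
            predicate=entry["predicate"],
            prediction=entry["prediction"],
            priority=int(entry.get("priority", 0)),
        )
        if rule.substrate not in ALL_SUBSTRATES:
            raise RuleError(
                f"rule {rule.name}: unknown substrate {rule.substrate!r}"
            )
        if rule.prediction not in PREDICTIONS:
            raise RuleError(
                f"rule {rule.name}: unknown prediction {rule.prediction!r}"
            )
        _validate_predicate(rule.predicate, catalog, rule.name)
        rules.append(rule)
    # statically reject same-scope same-priority conflicts
    seen: dict[tuple[str, str, int], str] = {}
    for r in rules:
        key = (r.species, r.substrate, r.priority)
        if key in seen and seen[key] != r.prediction:
            raise RuleError(
                f"conflicting rules at equal priority for {key}"
            )
        seen[key] = r.prediction
    return RuleSet(rules=tuple(rules))


def default_rules(catalog: Catalog) -> RuleSet:
    """The shipped rule set, validated against the given catalog."""
    raw = yaml.safe_load(
        (resources.files("hmoscreen.data") / "default_rules.yaml").read_text()
    )
    return parse_rules(raw, catalog)


def predict_growth(
    genotype: StrainGenotype,
    ruleset: RuleSet,
    catalog: Catalog,
    substrates: Sequence[str] = SUBSTRATES,
) -> list[PredictionRecord]:
    """One prediction per substrate: highest-priority satisfied rule wins.

    Raises when two satisfied rules at the winning priority disagree, or
    when no rule at all is satisfied for a substrate (the shipped defaults
    include always-true no-growth fallbacks, so this indicates a broken
    custom config).
    """
    records: list[PredictionRecord] = []
    for substrate in substrates:
        candidates = ruleset.applicable(genotype.species, substrate)
        if not candidates:
            raise RuleError(
                f"no rules applicable to ({genotype.species}, {substrate})"
            )
        winner: Rule | None = None
        winner_trace: tuple[str, ...] = ()
        i = 0
        while i < len(candidates) and winner is None:
            priority = candidates[i].priority
            tier = [c for c in candidates if c.priority == priority]
            satisfied = []
            for rule in tier:
                ok, trace = evaluate_predicate(
                    rule.predicate, genotype, catalog)
                if ok:
                    satisfied.append((rule, trace))
            if satisfied:
                predictions = {r.prediction for r, _ in satisfied}
                if len(predictions) > 1:
                    names = ", ".join(r.name for r, _ in satisfied)
                    raise RuleError(
                        f"conflicting satisfied rules at priority "
                        f"{priority}: {names}"
                    )
                winner, winner_trace = satisfied[0]
            i += len(tier)
        if winner is None:
            raise RuleError(
                f"no rule satisfied for ({genotype.species}, {substrate})"
            )
        records.append(
            PredictionRecord(
                strain_id=genotype.strain_id,
                substrate=substrate,
                predicted=winner.prediction,
                rule_name=winner.name,
                rule_trace=winner_trace,
            )
        )
    return records
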