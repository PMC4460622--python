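"""End-to-end orchestration: query -> match -> expand -> lattice -> prune.

`refine_hoi` composes the whole refinement session deterministically; with
a feedback oracle it finishes by putting the surviving candidate list to
the oracle (most general candidates first), mirroring the workflow in which
the pruned-down candidate list is proposed to the clinician for final
acceptance or rejection.  `evaluate` computes sensitivity/specificity of a
predicted concept set against a gold set over an explicit universe.  A
click CLI exposes match / expand / lattice / refine / evaluate / simulate.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import click

from hoirefine.fca_core import (
    DEFAULT_CELL_LIMIT,
    build_context,
    enumerate_concepts,
    read_context_matrix,
)
from hoirefine.lexical_matcher import build_index, match_query
from hoirefine.ontology_store import (
    CyclicOntologyError,
    OntologyGraph,
    compute_closure,
    detect_cycles,
    load_obo,
    load_ontology_tsv,
    merge_on_xrefs,
)
from hoirefine.pruner import (
    FeedbackOracle,
    RefinementResult,
    classify_roles,
    traverse_and_prune,
)
from hoirefine.sqe_expander import HopMode, minimal_ancestor_cover, two_hop

logger = logging.getLogger(__name__)


@dataclass
class SessionConfig:
    """Knobs of one refinement session.

    threshold: pruning threshold on the coverage ratio (default 0.75 — an
    attribute at exactly the threshold is kept as candidate).
    hop_mode: 'closure' (full descendant closure per derivation round,
    default) or 'edge' (direct children only).
    seed: controls any randomized component (none in the core path; kept
    for reproducibility contracts).
    cell_limit: |G| x |M| cap for lattice enumeration.
    """

    threshold: float = 0.75
    hop_mode: HopMode = "closure"
    seed: int = 0
    cell_limit: int = DEFAULT_CELL_LIMIT

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.hop_mode not in ("closure", "edge"):
            raise ValueError(f"hop_mode must be 'closure' or 'edge', got {self.hop_mode}")
        if self.cell_limit <= 0:
            raise ValueError("cell_limit must be positive")


@dataclass
class EvaluationRow:
    """One condition's confusion counts and derived rates."""

    condition: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def evaluate(
    predicted: Iterable[str],
    gold_positive: Iterable[str],
    universe: Iterable[str],
    condition: str = "",
) -> EvaluationRow:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) over ``universe``.

    Degenerate denominators: Se = 0 when the gold set is empty, Sp = 1 when
    there are no negatives.
    """
    predicted, gold, universe = set(predicted), set(gold_positive), set(universe)
    if not gold <= universe:
        raise ValueError("gold set must be a subset of the universe")
    if not predicted <= universe:
        raise ValueError("predicted set must be a subset of the universe")
    tp = len(predicted & gold)
    fn = len(gold - predicted)
    fp = len(predicted - gold)
    tn = len(universe - (predicted | gold))
    se = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 1.0
    return EvaluationRow(
        condition=condition, tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=se, specificity=sp,
    )


def refine_hoi(
    query: str,
    graph: OntologyGraph,
    config: SessionConfig | None = None,
    oracle: FeedbackOracle | None = None,
) -> RefinementResult:
    """Run one full refinement session.

    Steps: lexical match -> two-round downward expansion of the matches ->
    formal context over matched ∪ derived with their strict super-concepts
    as attributes -> lattice enumeration -> top-down coverage pruning (one
    oracle question per lattice level) -> final review of the surviving
    candidate list by the oracle, most general candidates first, each
    rejection eliminating the subsumed region except independently
    supported concepts.  Deterministic given config and oracle.

    An empty match set yields an empty result with a warning, not an error.
    """
    config = config or SessionConfig()
    cycles = detect_cycles(graph)
    if cycles:
        raise CyclicOntologyError(cycles[0])
    closure = compute_closure(graph)
    index = build_index(graph)
    match = match_query(query, index)
    if not match.matched_ids:
        logger.warning("query %r matched no concept synonym", query)
        return classify_roles(
            set(),
            two_hop(set(), closure, config.hop_mode),
            [],
        )

    expansion = two_hop(match.matched_ids, closure, config.hop_mode)
    expansion.cover = minimal_ancestor_cover(match.matched_ids, closure)
    objects = expansion.second_hop  # matched ∪ derived
    context = build_context(objects, closure)

    if not context.attributes:
        # matches are roots: nothing to prune, nothing potential
        return classify_roles(match.matched_ids, expansion, [])

    lattice = enumerate_concepts(context, cell_limit=config.cell_limit)
    traversal = traverse_and_prune(
        lattice,
        objects,
        closure,
        threshold=config.threshold,
        oracle=oracle,
        supported=match.matched_ids,
    )

    eliminated = set(traversal.eliminated)
    if oracle is not None:
        # final review of the candidate list, most general first so one
        # rejection can dismiss a whole region with a single question
        supported = set(traversal.supported)
        pending = [
            d for d in traversal.decisions
            if d.status == "candidate" and d.attribute_id not in eliminated
        ]
        pending.sort(
            key=lambda d: (len(closure.strict_ancestors(d.attribute_id)),
                           d.attribute_id)
        )
        for d in pending:
            if d.attribute_id in eliminated:
                continue
            if oracle(d.attribute_id):
                d.status = "confirmed"
                supported.add(d.attribute_id)
            else:
                d.status = "rejected"
                shield = set(supported)
                for s in supported:
                    shield |= closure.strict_descendants(s)
                doomed = (
                    {d.attribute_id} | closure.strict_descendants(d.attribute_id)
                ) - shield
                eliminated |= doomed

    result = classify_roles(
        match.matched_ids, expansion, traversal.decisions, eliminated
    )
    result.supported = traversal.supported
    return result


# ---------------------------------------------------------------------------
# CLI


def _load_graph(paths: tuple[str, ...]) -> OntologyGraph:
    graphs = []
    for p in paths:
        if p.endswith(".obo"):
            graphs.append(load_obo(p))
        else:
            graphs.append(load_ontology_tsv(p))
    return merge_on_xrefs(graphs)


def _emit(payload: dict, out: str | None) -> None:
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if out:
        Path(out).write_text(text, encoding="utf-8")
    else:
        sys.stdout.write(text)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="log to stderr at INFO level")
def cli(verbose: bool) -> None:
    """Refine health-outcome-of-interest concept sets from free-text queries."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


_ontology_opt = click.option(
    "--ontology", "ontologies", multiple=True, required=True,
    help="ontology file (.obo or .tsv); repeatable, merged on xrefs",
)


@cli.command("match")
@_ontology_opt
@click.option("--query", required=True)
@click.option("--out", default=None)
def cli_match(ontologies: tuple[str, ...], query: str, out: str | None) -> None:
    """Lexical synonym matching only."""
    graph = _load_graph(ontologies)
    res = match_query(query, build_index(graph))
    _emit(
        {
            "query": query,
            "tokens": res.tokens,
            "matched": sorted(res.matched_ids),
            "per_synonym": {k: sorted(v) for k, v in res.per_synonym_hits.items()},
        },
        out,
    )


@cli.command("expand")
@_ontology_opt
@click.option("--query", required=True)
@click.option("--hop-mode", type=click.Choice(["closure", "edge"]), default="closure")
@click.option("--out", default=None)
def cli_expand(
    ontologies: tuple[str, ...], query: str, hop_mode: str, out: str | None
) -> None:
    """Match then expand downward (2-hop) and compute the ancestor cover."""
    graph = _load_graph(ontologies)
    closure = compute_closure(graph)
    res = match_query(query, build_index(graph))
    exp = two_hop(res.matched_ids, closure, hop_mode)  # type: ignore[arg-type]
    cover = minimal_ancestor_cover(res.matched_ids, closure)
    _emit(
        {
            "query": query,
            "matched": sorted(res.matched_ids),
            "first_hop": sorted(exp.first_hop),
            "second_hop": sorted(exp.second_hop),
            "cover": sorted(cover),
        },
        out,
    )


@cli.command("lattice")
@click.option("--context", "context_path", required=True, help="0/1 matrix TSV")
@click.option("--out", default=None)
def cli_lattice(context_path: str, out: str | None) -> None:
    """Enumerate the formal concepts of a context matrix file."""
    K = read_context_matrix(context_path)
    lattice = enumerate_concepts(K)
    _emit(
        {
            "n_objects": K.n_objects,
            "n_attributes": K.n_attributes,
            "concepts": [
                {"extent": sorted(c.extent), "intent": sorted(c.intent)}
                for c in lattice.concepts
            ],
            "hasse": [list(e) for e in lattice.hasse],
        },
        out,
    )


def _make_oracle(spec: str | None) -> FeedbackOracle | None:
    if spec is None:
        return None
    if spec.startswith("gold:"):
        path = Path(spec[len("gold:"):])
        accepted = {
            line.strip()
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
        return lambda cid: cid in accepted
    if spec == "interactive":
        def ask(cid: str) -> bool:
            return click.confirm(f"accept concept {cid}?", default=True)
        return ask
    raise click.BadParameter(f"unknown oracle spec {spec!r}")


@cli.command("refine")
@_ontology_opt
@click.option("--query", required=True)
@click.option("--threshold", type=float, default=0.75, show_default=True)
@click.option("--hop-mode", type=click.Choice(["closure", "edge"]), default="closure")
@click.option("--oracle", "oracle_spec", default=None,
              help="'gold:<file>' (accept iff listed) or 'interactive'")
@click.option("--seed", type=int, default=0)
@click.option("--out", default=None)
def cli_refine(
    ontologies: tuple[str, ...],
    query: str,
    threshold: float,
    hop_mode: str,
    oracle_spec: str | None,
    seed: int,
    out: str | None,
) -> None:
    """Full refinement session: match, expand, build lattice, prune."""
    if not 0.0 <= threshold <= 1.0:
        raise click.BadParameter("threshold must be between 0 and 1")
    graph = _load_graph(ontologies)
    config = SessionConfig(threshold=threshold, hop_mode=hop_mode, seed=seed)  # type: ignore[arg-type]
    result = refine_hoi(query, graph, config, _make_oracle(oracle_spec))
    for d in result.decisions:
        logger.info(
            "decision %s ratio=%.3f (%d/%d) %s",
            d.attribute_id, d.ratio, d.n_covered, d.n_sub, d.status,
        )
    _emit(result.to_dict(query), out)


@cli.command("evaluate")
@click.option("--predicted", required=True, help="file: one concept id per line")
@click.option("--gold", required=True, help="file: one concept id per line")
@click.option("--universe", required=True, help="file: one concept id per line")
@click.option("--condition", default="")
@click.option("--out", default=None)
def cli_evaluate(
    predicted: str, gold: str, universe: str, condition: str, out: str | None
) -> None:
    """Sensitivity/specificity of a predicted set against a gold set."""
    def read_ids(p: str) -> set[str]:
        return {
            line.strip()
            for line in Path(p).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }

    row = evaluate(read_ids(predicted), read_ids(gold), read_ids(universe), condition)
    _emit(row.to_dict(), out)


@cli.command("simulate")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-concepts", type=int, default=120, show_default=True)
@click.option("--outdir", required=True)
def cli_simulate(seed: int, n_concepts: int, outdir: str) -> None:
    """Emit a synthetic ontology TSV, query, gold file and expected result."""
    from hoirefine.synthetic_fixtures import (
        FixtureSpec,
        generate_dag_ontology,
        plant_hoi,
        write_ontology_tsv,
    )

    spec = FixtureSpec(n_concepts=n_concepts, seed=seed)
    graph = generate_dag_ontology(spec)
    query_terms, gold = plant_hoi(graph, seed=seed)
    outp = Path(outdir)
    outp.mkdir(parents=True, exist_ok=True)
    write_ontology_tsv(graph, outp / "ontology.tsv")
    (outp / "query.txt").write_text(" ".join(query_terms) + "\n", encoding="utf-8")
    (outp / "gold.txt").write_text("\n".join(sorted(gold)) + "\n", encoding="utf-8")
    result = refine_hoi(
        " ".join(query_terms), graph, SessionConfig(seed=seed),
        oracle=lambda cid: cid in gold,
    )
    _emit(result.to_dict(" ".join(query_terms)), str(outp / "expected.json"))
    click.echo(f"fixture written to {outp}")


def run_cli(argv: list[str] | None = None) -> int:
    """Entry point returning an exit code instead of raising SystemExit."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except SystemExit as e:  # click uses SystemExit for --help etc.
        return int(e.code or 0)
    except (click.ClickException, click.Abort) as e:
        if isinstance(e, click.ClickException):
            e.show(file=sys.stderr)
        return 2
    except (ValueError, OSError) as e:
        print(f"error: {e}", file=sys.stderr)
        return 1


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(run_cli())
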