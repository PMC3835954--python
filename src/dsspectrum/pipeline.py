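"""End-to-end spectrum-of-activity analysis and report writing.

Given a trigger dsRNA and a family of non-target orthologs (plus optional
bioassay tables), the pipeline computes per-ortholog specificity metrics
(percent identity, SNPs, shared 21-nt windows, longest run, activity call),
the identity-distance UPGMA tree, and the bioassay statistics, and writes
TSV + JSON + Newick outputs. Identical config, inputs and seeds produce
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import seq_io
from .alignment import (
    AlignedPair,
    AlignmentParams,
    count_snps,
    global_align,
    pair_from_gapped,
    percent_identity,
    round_half_up,
)
from .bioassay_stats import (
    DoseResponseData,
    TwoGroupCounts,
    fisher_exact,
    fit_probit,
    levene_test,
    two_sample_t,
)
from .errors import ValidationError
from .match_stats import DEFAULT_K, predict_activity, shared_window_count
from .phylogenetics import identity_distance_matrix, upgma
from .seq_io import BioassayRow, SequenceRecord

logger = logging.getLogger("dsspectrum")

ALPHA = 0.05


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; every referenced path must exist."""

    trigger_path: str
    orthologs_path: str
    out_dir: str
    bioassay_path: str | None = None
    prealigned: bool = False
    k: int = DEFAULT_K
    alignment_params: AlignmentParams = field(default_factory=AlignmentParams)
    estimate_c: bool = True
    max_expression: float | None = None  # ng/g tissue, for margins of exposure
    seed: int = 0


@dataclass(frozen=True)
class OrthologRow:
    species: str
    percent_identity: float
    percent_identity_exact: float
    n_snps: int
    n_k_matches: int
    longest_run: int
    predicted_active: bool
    rationale: str


@dataclass
class SpectrumReport:
    trigger_id: str
    k: int
    rows: list[OrthologRow]
    newick: str
    bioassay: dict
    margins: dict[str, float]


def margin_of_exposure(tested_conc: float, max_expression: float) -> float:
    """Fold ratio between a tested diet concentration and the maximum
    measured tissue expression, reported to 1 decimal."""
    if tested_conc <= 0 or max_expression <= 0:
        raise ValidationError("margin_of_exposure requires positive inputs")
    return round_half_up(tested_conc / max_expression, 1)


def _stage(name: str, t0: float, **params):
    logger.info(
        "stage=%s elapsed=%.3fs %s",
        name,
        time.perf_counter() - t0,
        " ".join(f"{k}={v}" for k, v in params.items()),
    )


def analyze_pair(trigger_id: str, species: str, pair: AlignedPair, k: int) -> OrthologRow:
    profile = shared_window_count(pair, k=k)
    call = predict_activity(profile, threshold_k=k)
    return OrthologRow(
        species=species,
        percent_identity=percent_identity(pair, rounded=True),
        percent_identity_exact=percent_identity(pair, rounded=False),
        n_snps=count_snps(pair),
        n_k_matches=profile.m,
        longest_run=profile.longest_run,
        predicted_active=call.predicted_active,
        rationale=call.rationale,
    )


def _bioassay_summaries(rows: list[BioassayRow], estimate_c: bool) -> dict:
    out: dict = {}
    by_species: dict[str, list[BioassayRow]] = {}
    for r in rows:
        by_species.setdefault(r.species, []).append(r)
    for species, srows in sorted(by_species.items()):
        entry: dict = {}
        test = [r for r in srows if r.treatment == "test"]
        ctrl = [r for r in srows if r.treatment == "control"]
        pos_doses = sorted({r.dose for r in test if r.dose > 0})
        if len(pos_doses) >= 3:
            data = DoseResponseData.from_rows(srows)
            fit = fit_probit(data, estimate_c=estimate_c)
            entry["endpoint"] = "dose_response"
            entry["probit"] = {
                "lc50": fit.lc50,
                "lc50_2sf": float(f"{fit.lc50:.2g}") if fit.converged else None,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "slope": fit.b,
                "natural_mortality": fit.c,
                "converged": fit.converged,
            }
        elif test and ctrl:
            n_t = sum(r.n_exposed for r in test)
            d_t = sum(r.n_dead for r in test)
            n_c = sum(r.n_exposed for r in ctrl)
            d_c = sum(r.n_dead for r in ctrl)
            p = fisher_exact(
                TwoGroupCounts(
                    labels=("control", "test"), n_total=(n_c, n_t), n_event=(d_c, d_t)
                )
            )
            entry["endpoint"] = "survival"
            entry["fisher"] = {
                "p_value": p,
                "significant": p < ALPHA,
                "control_mortality": d_c / n_c if n_c else None,
                "test_mortality": d_t / n_t if n_t else None,
                "no_observed_effect_conc": (
                    max((r.dose for r in test), default=None) if p >= ALPHA else None
                ),
            }
        ev_t = [r.endpoint_value for r in test if r.endpoint_value is not None]
        ev_c = [r.endpoint_value for r in ctrl if r.endpoint_value is not None]
        if len(ev_t) >= 2 and len(ev_c) >= 2:
            w, p_lev = levene_test(ev_c, ev_t)
            t, p_t = two_sample_t(ev_c, ev_t)
            entry["continuous"] = {
                "levene_W": w,
                "levene_p": p_lev,
                "t": t,
                "t_p": p_t,
                "significant": p_t < ALPHA,
            }
        if entry:
            out[species] = entry
    return out


def run_spectrum_report(config: RunConfig) -> SpectrumReport:
    """Run the full analysis and write report.tsv, report.json, tree.nwk."""
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.prealigned:
        gapped = seq_io.read_gapped_fasta(config.orthologs_path)
        trig_gapped = seq_io.read_gapped_fasta(config.trigger_path)[0]
        trigger = trig_gapped.ungapped()
        records = [g.ungapped() for g in gapped]
        pairs = {
            (trigger.id, g.id): pair_from_gapped(trig_gapped, g) for g in gapped
        }
    else:
        trigger = seq_io.read_fasta(config.trigger_path)[0]
        records = seq_io.read_fasta(config.orthologs_path)
        pairs = {
            (trigger.id, r.id): global_align(trigger, r, config.alignment_params)
            for r in records
        }
    _stage("align", t0, trigger=trigger.id, n_orthologs=len(records), k=config.k)

    rows = [
        analyze_pair(trigger.id, r.id, pairs[(trigger.id, r.id)], config.k)
        for r in records
    ]
    _stage("match_stats", t0, n_rows=len(rows))

    # tree over trigger + orthologs needs every pairwise alignment
    taxa: list[SequenceRecord] = [trigger] + [r for r in records if r.id != trigger.id]
    all_pairs = dict(pairs)
    for x, y in itertools.combinations(taxa, 2):
        if (x.id, y.id) not in all_pairs and (y.id, x.id) not in all_pairs:
            all_pairs[(x.id, y.id)] = global_align(x, y, config.alignment_params)
    newick = ""
    if len(taxa) >= 2:
        matrix = identity_distance_matrix([t.id for t in taxa], all_pairs)
        tree = upgma(matrix)
        newick = seq_io.newick_string(tree)
        seq_io.write_newick(tree, out_dir / "tree.nwk")
    _stage("tree", t0, n_taxa=len(taxa))

    bioassay: dict = {}
    if config.bioassay_path:
        brows = seq_io.read_bioassay_table(config.bioassay_path)
        bioassay = _bioassay_summaries(brows, estimate_c=config.estimate_c)
        _stage("bioassay", t0, n_rows=len(brows), n_species=len(bioassay))

    margins: dict[str, float] = {}
    if config.max_expression is not None and config.bioassay_path:
        tested = sorted(
            {r.dose for r in brows if r.treatment == "test" and r.dose > 0}
        )
        margins = {
            f"{dose:g}": margin_of_exposure(dose, config.max_expression)
            for dose in tested
        }

    report = SpectrumReport(
        trigger_id=trigger.id,
        k=config.k,
        rows=rows,
        newick=newick,
        bioassay=bioassay,
        margins=margins,
    )
    write_report(report, out_dir)
    _stage("write", t0, out_dir=str(out_dir))
    return report


def write_report(report: SpectrumReport, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_lines = [
        "species\tpercent_identity\tn_snps\tn_k_matches\tlongest_run\tpredicted_active"
    ]
    for r in report.rows:
        tsv_lines.append(
            f"{r.species}\t{r.percent_identity:.1f}\t{r.n_snps}\t"
            f"{r.n_k_matches}\t{r.longest_run}\t{'yes' if r.predicted_active else 'no'}"
        )
    (out_dir / "report.tsv").write_text("\n".join(tsv_lines) + "\n")

    payload = {
        "trigger": report.trigger_id,
        "k": report.k,
        "orthologs": [asdict(r) for r in report.rows],
        "tree_newick": report.newick,
        "bioassay": report.bioassay,
        "margins_of_exposure": report.margins,
    }
    (out_dir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
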