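"""Structured extraction reports.

The report is the machine-readable audit trail of every decision the
pipeline makes for a batch of records: screening, carbon-group verdicts
with full modification-count breakdowns, and the assembled fragments.
Reports are JSON-serializable, versioned, and deterministic: two runs on
the same input with the same configuration produce identical documents.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable, Sequence

from .extract import RecordAnalysis
from .molio import RecordError

SCHEMA_VERSION = 1


def _breakdown_dict(breakdown) -> dict:
    return {
        "per_carbon": [
            {
                "atom": pc.atom_index,
                "replacement": pc.replacement,
                "unsaturation": pc.unsaturation,
            }
            for pc in breakdown.per_carbon
        ],
        "n_ring": breakdown.n_ring,
        "n_extra_carbonyl": breakdown.n_extra_carbonyl,
        "n_anomer_penalty": breakdown.n_anomer_penalty,
        "n_mod": breakdown.n_mod,
    }


def record_dict(record_id: str, analysis: RecordAnalysis) -> dict:
    groups = []
    for ga in analysis.groups:
        entry: dict = {
            "n_c": ga.group.n_c,
            "branch_count": ga.group.branch_count,
            "carbon_indices": sorted(ga.group.carbon_indices),
            "passed": ga.verdict.passed,
            "failed_conditions": sorted(ga.verdict.failed_conditions),
        }
        if ga.best_chain is not None:
            entry["main_chain"] = {
                "carbons": list(ga.best_chain.ordered_carbons),
                "branch_carbons": sorted(ga.best_chain.branch_carbons),
                "anomeric_status": ga.best_chain.anomeric_status,
                "anomeric_position": ga.best_chain.anomeric_position,
            }
            entry["threshold"] = ga.threshold
            entry["modification_count"] = _breakdown_dict(ga.breakdown)
        groups.append(entry)
    fragments = []
    for f in analysis.fragments:
        fragments.append(
            {
                "smiles": f.smiles,
                "n_backbones": len(f.backbones),
                "backbones": [
                    {
                        "length": bb.chain.length,
                        "n_c": bb.group.n_c,
                        "anomeric_status": bb.chain.anomeric_status,
                        "n_mod": bb.breakdown.n_mod,
                    }
                    for bb in f.backbones
                ],
                "n_excision_caps": len(f.excision_caps),
                "n_retained_modifications": len(f.modifications),
                "n_aglycone_atoms": len(f.aglycone_atoms),
            }
        )
    return {
        "id": record_id,
        "screening": asdict(analysis.screening),
        "has_glycan": bool(analysis.fragments),
        "rejection_category": analysis.rejection_category,
        "groups": groups,
        "fragments": fragments,
    }


def build_report(
    analyses: Sequence[tuple[str, RecordAnalysis]],
    errors: Sequence[RecordError] = (),
) -> dict:
    records = [record_dict(rid, a) for rid, a in analyses]
    return {
        "schema_version": SCHEMA_VERSION,
        "n_records": len(records),
        "n_with_glycan": sum(r["has_glycan"] for r in records),
        "n_fragments": sum(len(r["fragments"]) for r in records),
        "errors": [asdict(e) for e in errors],
        "records": records,
    }


def dump_report(report: dict, fh) -> None:
    json.dump(report, fh, indent=1, sort_keys=True)
    fh.write("\n")


def summarize(tagged_reports: Iterable[tuple[str, dict]]) -> list[tuple]:
    """Category summary rows: (category, n entries, n with glycans).

    Accepts (category, report) pairs and appends a total row; row counts
    are additive over the per-record glycan indicators.
    """
    rows: dict[str, list[int]] = {}
    for category, report in tagged_reports:
        row = rows.setdefault(category, [0, 0])
        row[0] += report["n_records"]
        row[1] += report["n_with_glycan"]
    out = [(cat, n, g) for cat, (n, g) in sorted(rows.items())]
    if out:
        out.append(
            ("total", sum(r[1] for r in out), sum(r[2] for r in out))
        )
    return out


def summary_tsv(rows: Sequence[tuple]) -> str:
    lines = ["category\tn_entries\tn_with_glycan"]
    lines += [f"{c}\t{n}\t{g}" for c, n, g in rows]
    return "\n".join(lines) + "\n"
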