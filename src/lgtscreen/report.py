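"""Deterministic rendering of screen summaries (JSON / TSV / text)."""

from __future__ import annotations

import json

from .consensus import SummaryReport

FORMATS = ("json", "tsv", "text")


def render_summary(report: SummaryReport, format: str = "text") -> str:
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        return _render_tsv(report)
    return _render_text(report)


def parse_summary_json(text: str) -> SummaryReport:
    return SummaryReport.from_dict(json.loads(text))


def _flat_items(report: SummaryReport):
    data = report.to_dict()
    for key in sorted(data):
        value = data[key]
        if isinstance(value, dict):
            for sub in sorted(value, key=str):
                inner = value[sub]
                if isinstance(inner, dict):
                    for sub2 in sorted(inner, key=str):
                        yield f"{key}.{sub}.{sub2}", inner[sub2]
                else:
                    yield f"{key}.{sub}", inner
        else:
            yield key, value


def _render_tsv(report: SummaryReport) -> str:
    lines = ["key\tvalue"]
    lines += [f"{k}\t{v}" for k, v in _flat_items(report)]
    return "\n".join(lines) + "\n"


def _hist_block(title: str, hist: dict) -> list[str]:
    lines = [title]
    if not hist:
        return lines + ["  (none)"]
    width = max(len(str(k)) for k in hist)
    for key in sorted(hist, key=str):
        lines.append(f"  {str(key):<{width}}  {hist[key]}")
    lines.append(f"  {'total':<{width}}  {sum(hist.values())}")
    return lines


def _render_text(report: SummaryReport) -> str:
    lines = [
        "Inter-domain LGT screen summary",
        "===============================",
        f"genes analyzed            {report.n_genes}",
        f"gene trees (denominator)  {report.n_trees}",
        f"proteome size             {report.n_proteome}",
        f"LGT candidates (NJ)       {report.candidate_total}"
        f" ({report.pct_of_trees}% of trees, {report.pct_of_proteome}% of proteome)",
        f"confirmed by both methods {report.confirmed_total}"
        f" ({report.agreement_pct}% of candidates)",
        f"too few taxa for ML       {report.too_few_taxa}",
        f"direction conflicts       {report.conflicts}",
        "",
    ]
    lines += _hist_block("Direction of transfer (NJ candidates):", report.nj_direction_hist)
    lines.append("")
    lines += _hist_block("Direction of transfer (ML candidates):", report.ml_direction_hist)
    lines.append("")
    lines += _hist_block("Closest-neighbor phylum (NJ):", report.nj_donor_hist)
    lines.append("")
    lines += _hist_block("Closest-neighbor phylum (ML):", report.ml_donor_hist)
    lines += [
        "",
        "Origin totals (confirmed candidates):",
        f"  bacterial origin        {report.bacterial_origin_total}",
        f"  eukaryotic origin       {report.eukaryotic_total}",
        f"  archaea-to-bacteria     {report.archaea_export_total}",
        f"  inter-domain total      {report.interdomain_total}",
        "",
        f"NJ-inferred events (direction + only-archaea rescues): {report.nj_events_total}",
        f"ML trees with direction and good support:              {report.ml_good_support}",
        "",
    ]
    return "\n".join(lines)
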