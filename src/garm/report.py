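"""TXT and XML result writers.

Both writers present the same report: the run metadata and the ordered rule
list with all six metrics. TXT is one tab-separated line per rule under a
'#'-prefixed header block; XML is an indented document that re-parses into
the same numbers. Fractional metrics are printed to 4 decimal places with
banker's (half-even) rounding so repeated runs are byte-identical.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .miner import Rule, SearchConfig
from .table import DataTable


@dataclass(frozen=True)
class MiningReport:
    """Everything the writers need: inputs, configuration and results."""

    input_name: str
    pattern_text: str
    config: SearchConfig
    n_rows: int
    n_columns: int
    rules: tuple[Rule, ...]


def _f(x: float) -> str:
    return format(x, ".4f")  # CPython formats with round-half-even


def _threshold_items(config: SearchConfig) -> list[tuple[str, str]]:
    return [
        ("min_support", str(config.min_support)),
        ("min_confidence", _f(config.min_confidence)),
        ("min_lift", _f(config.min_lift)),
        ("min_leverage", _f(config.min_leverage)),
        ("max_value_set_size", str(config.max_value_set_size)),
        ("simplify_tolerance", _f(config.simplify_tolerance)),
    ]


def write_txt(report: MiningReport, sink) -> None:
    """One rule per line: text, then TAB-separated metrics."""
    w = sink.write
    w("# garm association rule mining report\n")
    w(f"# input: {report.input_name}\n")
    w(f"# pattern: {report.pattern_text}\n")
    w(f"# rows: {report.n_rows}\n")
    w(f"# columns: {report.n_columns}\n")
    for key, val in _threshold_items(report.config):
        w(f"# {key}: {val}\n")
    w(f"# rules: {len(report.rules)}\n")
    w("# fields: rule\tsupport\tlhs_support\trhs_support\tconfidence\tlift\tleverage\n")
    for rule in report.rules:
        m = rule.metrics
        w(
            f"{rule.text}\t{m.support}\t{m.lhs_support}\t{m.rhs_support}"
            f"\t{_f(m.confidence)}\t{_f(m.lift)}\t{_f(m.leverage)}\n"
        )


def build_xml(report: MiningReport, table: DataTable) -> ET.ElementTree:
    root = ET.Element("garm_results")
    meta = ET.SubElement(
        root,
        "meta",
        pattern=report.pattern_text,
        input=report.input_name,
        n_rows=str(report.n_rows),
        n_columns=str(report.n_columns),
    )
    ET.SubElement(meta, "thresholds", dict(_threshold_items(report.config)))
    rules_el = ET.SubElement(root, "rules")
    for rule in report.rules:
        rule_el = ET.SubElement(rules_el, "rule", text=rule.text)
        lhs_el = ET.SubElement(rule_el, "lhs")
        for clause in rule.clauses:
            cl_el = ET.SubElement(lhs_el, "clause")
            for eq in clause:
                ET.SubElement(
                    cl_el,
                    "eq",
                    column=table.columns[eq.column].name,
                    values="".join(eq.values),
                )
        rhs_el = ET.SubElement(rule_el, "rhs")
        ET.SubElement(
            rhs_el,
            "eq",
            column=table.columns[rule.rhs.column].name,
            values="".join(rule.rhs.values),
        )
        m = rule.metrics
        ET.SubElement(
            rule_el,
            "metrics",
            support=str(m.support),
            lhs_support=str(m.lhs_support),
            rhs_support=str(m.rhs_support),
            confidence=_f(m.confidence),
            lift=_f(m.lift),
            leverage=_f(m.leverage),
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    return tree


def write_xml(report: MiningReport, table: DataTable, sink) -> None:
    tree = build_xml(report, table)
    buf = io.BytesIO()
    tree.write(buf, encoding="utf-8", xml_declaration=True)
    sink.write(buf.getvalue().decode("utf-8") + "\n")


def txt_string(report: MiningReport) -> str:
    buf = io.StringIO()
    write_txt(report, buf)
    return buf.getvalue()


def xml_string(report: MiningReport, table: DataTable) -> str:
    buf = io.StringIO()
    write_xml(report, table, buf)
    return buf.getvalue()
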