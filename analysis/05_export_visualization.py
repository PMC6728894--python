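#!/usr/bin/env python
"""Export the group findings as BrainNetViewer-style .node/.edge files.

Re-reads the report from script 04 and writes whitespace-delimited node
and edge files (synthetic atlas coordinates) that a surface-rendering tool
can consume directly.
"""

import importlib
import json
from pathlib import Path

from fcgraph.atlas import synthetic_atlas
from fcgraph.groupstats import EdgeFinding
from fcgraph.io import export_brainnetviewer

ROOT = Path(__file__).resolve().parents[1]
REPORT = ROOT / "results" / "group_run" / "report.json"


def main():
    if not REPORT.exists():
        importlib.import_module("04_group_statistics").main()
    with open(REPORT) as fh:
        report = json.load(fh)
    findings = [EdgeFinding(**f) for f in report["edge_findings"]]
    nodal = {r["metric"]: abs(r["t_observed"]) for r in report["nodal_tests"]}
    labels = report["region_labels"]
    atlas = synthetic_atlas(len(labels)).assign(label=labels)
    node_p, edge_p = export_brainnetviewer(
        findings, nodal, atlas,
        ROOT / "results" / "findings.node",
        ROOT / "results" / "findings.edge",
    )
    print(f"wrote {node_p} ({len(nodal)} highlighted regions)")
    print(f"wrote {edge_p} ({len(findings)} signed edges)")


if __name__ == "__main__":
    main()
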