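"""End-to-end pipeline run: simulate -> analyze -> report.

Equivalent to the CLI:

    tremornet simulate --out run/cohort --seed 8
    tremornet analyze --cohort run/cohort --out run/results --seed 8
    tremornet report --results run/results

but driven from Python with a small cohort so it finishes in ~10 s.
"""

import json
import tempfile
from pathlib import Path

from tremornet import RunConfig, SynthConfig
from tremornet.pipeline import run_analyze, run_report, run_simulate

config = RunConfig(
    synth=SynthConfig(n_control=3, n_et=3, n_trials_per_subject=8, seed=8),
    n_permutations=200,
    seed=8,
)

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    manifest = run_simulate(config, root / "cohort")
    print(f"simulated {manifest['n_trials']} trials "
          f"(cohort sha256 {manifest['cohort_sha256'][:12]}...)")

    summary = run_analyze(config, root / "cohort", root / "results")
    shares = summary["explained_variance"]
    print("tfPCA explained variance:", ", ".join(f"{v:.1%}" for v in shares))
    print(f"FDR-surviving group clusters: {summary['n_fdr_significant_group_clusters']}")

    report = run_report(root / "results")
    print(json.dumps({k: v["status"] for k, v in report["sections"].items()}, indent=2))

# At this cohort size the group contrast is underpowered (clusters rarely
# survive FDR); the statistics CSVs, tremor table, coherence overlap map and
# the serialized tfPCA model are written alongside the JSON/text report.
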