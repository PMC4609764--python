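"""File-based workflow: corpus CSV in, JSON report out.

Equivalent to `pcurve-meta simulate` followed by `pcurve-meta analyze`.
"""

import tempfile
from pathlib import Path

from pcurve_meta import (
    GeneratorConfig,
    generate_trials,
    read_studies_csv,
    run_full_analysis,
    write_studies_csv,
)

workdir = Path(tempfile.mkdtemp())
corpus_csv = workdir / "corpus.csv"
report_json = workdir / "report.json"

write_studies_csv(generate_trials(GeneratorConfig(seed=12345)), corpus_csv)
studies = read_studies_csv(corpus_csv)
report = run_full_analysis(studies)
report.to_json(report_json)

m = report.meta
print(f"read {len(studies)} studies from {corpus_csv.name}")
print(f"pooled d = {m.pooled_d:.3f} (95% CI {m.ci_low:.3f} to {m.ci_high:.3f}); "
      f"I^2 = {m.i2:.1f}%")
if report.pcurve is not None:
    print(f"p-curve inference: {report.pcurve.inference} "
          f"({report.pcurve.n_significant} studies included)")
else:
    print(f"p-curve undefined: {report.pcurve_error}")
print(f"report written to {report_json} "
      f"(input digest {report.provenance['input_digest'][:12]}...)")
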