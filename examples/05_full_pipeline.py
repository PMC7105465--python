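"""One-call end-to-end run on the packaged noiseless cell scenario.

The scenario plants 62 differential proteins (46 down, 16 up) among 300
mitochondrial proteins with no noise; the pipeline must report exactly those
counts, demonstrating that the whole chain (simulate -> normalize -> roll up
-> Filter 1 -> Filter 2 -> enrichment) is lossless in the noiseless limit.
"""

import json
import tempfile
from pathlib import Path

from mitodep.pipeline import run_all
from mitodep.presets import cell_scenario

out = Path(tempfile.mkdtemp()) / "run"
manifest = run_all(cell_scenario(), seed=1, out_dir=out)

summary = json.loads((out / "summary.json").read_text())
print("mtDEP summary:", summary["mtdeps"])
print("confidence classes:", summary["confidence_classes"])
print("outputs:", sorted(manifest.checksums))
print("config hash:", manifest.config_hash[:12],
      "| re-running with the same seed reproduces identical checksums")
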