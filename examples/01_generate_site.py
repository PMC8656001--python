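"""Generate one synthetic stroke-care site in the common data model.

Draws patient journeys from the built-in Code-Stroke-like pathway model
(ER admission -> first attention -> CT -> possible reperfusion ->
discharge -> possible hospital and long-stay episodes), injects realistic
timestamp-quality defects, and writes the four CDM tables plus the
ground-truth ledger.
"""

import tempfile
from pathlib import Path

from carepath import generate_dataset, validate_cdm, write_site
from carepath.synthdata import DefectConfig

dataset, truth = generate_dataset(
    n_cases=200, defects=DefectConfig(), site_id="DEMO", seed=42
)

out = Path(tempfile.mkdtemp()) / "demo-site"
write_site(dataset, truth, out)

report = validate_cdm(dataset)
print(f"wrote site {dataset.site_id!r} to {out}")
print(f"  patients : {len(dataset.patients)}")
print(f"  episodes : {len(dataset.episodes)}")
print(f"  events   : {len(dataset.events)}")
print(f"  validation issues: {len(report.issues)}")
print(f"  injected defects : {len(truth.defects)} "
      f"({sorted({d['kind'] for d in truth.defects})})")
# One journey = one patient here; episodes > patients because transfers to
# the acute or long-stay hospital open new episodes. The defect counts are
# the ground truth that recovery tests reconcile against.
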