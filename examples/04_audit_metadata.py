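"""Cohort audit: value counts of a metadata field.

Writes the synthetic stand-in of the survey's sample metadata (the
published cohort composition: 3569 sponge specimens, 370 seawater, 65
sediment samples, and the minor categories) and audits it the way the
CLI's `ampliquery audit` does.
"""

import tempfile
from pathlib import Path

from ampliquery import read_sample_metadata, summarize_metadata, write_sample_metadata
from ampliquery.synthetic_data import synthetic_cohort_metadata

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sample.metadata"
    write_sample_metadata(synthetic_cohort_metadata(), path)
    metadata = read_sample_metadata(path)
    counts = summarize_metadata(metadata, "sample_type")

print(f"{metadata.n_samples} samples")
for value, n in sorted(counts.items(), key=lambda kv: -kv[1]):
    print(f"  {value:<18}{n:>6}")
print("\nCounts sum to the full cohort; missing cells would be excluded.")
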