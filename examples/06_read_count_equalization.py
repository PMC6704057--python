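"""Equalize per-sample read counts by seeded subsampling.

Detection sensitivity depends on sequencing depth, so before alignment
every sample is randomly downsampled, without replacement, to the cohort
minimum.  Works on any read collections; a FASTQ wrapper
(memflex.enrichment.subsample_fastq) handles plain or gzipped files.
"""

from memflex import equalize_read_counts

samples = {
    "ctrl_rep1": [f"read_{i}" for i in range(120_000)],
    "ctrl_rep2": [f"read_{i}" for i in range(95_000)],
    "ltp_rep1": [f"read_{i}" for i in range(110_000)],
}
equalized = equalize_read_counts(samples, seed=42)
for name in samples:
    print(f"{name}: {len(samples[name]):>7} -> {len(equalized[name]):>6} reads")

# All samples end at the minimum (95 000); every retained read existed in
# its source sample, and the same seed reproduces the same subsets.
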