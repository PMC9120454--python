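"""Calibrate a minimum seed length from a bimodal host-mapping SAM.

Reads mapped to a host genome split into full-length true host reads
and short-overlap spurious mappings from regions shared between host
and bacterial genomes. This script simulates such a population, writes
it as SAM, detects the valley between the two match-length modes,
calibrates the 95th-percentile seed threshold and reports the host
fraction before and after filtering.
"""

import tempfile
from pathlib import Path

from gutbench import (
    ReadPopulationSpec,
    calibrate,
    host_fraction,
    mapq_peak_summary,
    match_length_distribution,
    read_alignments,
    simulate_alignment_records,
    write_sam,
)

spec = ReadPopulationSpec(n_true_host=500, n_short_fp=2000, n_unmapped=7500, seed=3)
readset = simulate_alignment_records(spec)

with tempfile.TemporaryDirectory() as tmp:
    sam = Path(tmp) / "host.sam"
    write_sam(readset, sam, seed=3)
    records = read_alignments(sam, min_read_length=140)

dist = match_length_distribution(records)
cal = calibrate(dist, percentile=0.95)
print(f"mapped reads                {dist.n_mapped} of {dist.n_total}")
print(f"valley split point          {cal.split_point} bases")
print(f"short-overlap population    {len(cal.fp_lengths)} reads")
print(f"calibrated minimum seed     {cal.recommended_seed} bases")

naive = host_fraction(records, seed=1, sample_id="sim")
filtered = host_fraction(records, seed=cal.recommended_seed, sample_id="sim")
print(f"host fraction, unfiltered   {naive.host_fraction:5.2f} %")
print(f"host fraction, calibrated   {filtered.host_fraction:5.2f} %")
print(f"MAPQ peaks                  {mapq_peak_summary(records)}")
print()
print("The unfiltered fraction counts every mapped read as host material;")
print("raising the seed threshold to the calibrated value removes 95% of the")
print("short-overlap population while keeping every full-length host read,")
print("bringing the host fraction down close to the true 5% (500 of 10000).")
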