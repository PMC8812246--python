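"""Run the detection pipeline on the simulated sample from example 01.

Scans the alignments once for the three evidence classes (spliced reads,
chimeric pairs, chimeric reads), nominates retrocopy candidates, clusters
the distal evidence and resolves the insertion site.  Run example 01
first (or this script will build its inputs itself).
"""

import subprocess
import sys
from pathlib import Path

out = Path("example_output")
if not (out / "sample.sam").exists():
    subprocess.run([sys.executable, "examples/01_simulate_retrocopy_sample.py"], check=True)

from retroscan import build_junction_index, read_gene_annotation, scan_alignments
from retroscan.calling import call_sample

genes = read_gene_annotation(out / "genes.gtf")
index = build_junction_index(genes)
ev = scan_alignments(out / "sample.sam", index)
print(f"evidence: {len(ev.spliced)} spliced reads, {len(ev.pairs)} chimeric pairs, "
      f"{len(ev.clips)} chimeric reads (of {ev.reads_seen} records scanned)")

result = call_sample(ev, index, sample_id="demo")
for cand in result.candidates:
    print(f"candidate: {cand.gene_name} with {cand.total_sr} spliced reads over "
          f"{cand.distinct_junctions} junctions "
          f"({cand.fraction_junctions_covered:.0%} of the gene's junctions)")
for site in result.sites:
    print(f"insertion site: {site.chrom}:{site.start + 1}-{site.end} "
          f"[{site.tier}] CP={site.cp_count} CR={site.cr_count} "
          f"{site.feature}, orientation={site.orientation}, "
          f"TSD estimate={site.metadata.get('tsd_len', 'NA')} bp")
# The CP-CR tier means both discordant pairs and split reads support the
# site; the interval spans the two breakpoints, so its width minus one is
# the target-site duplication length.
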