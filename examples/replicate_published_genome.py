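"""Replicate the published mitogenome statistics from local GenBank records.

Usage:
    python examples/replicate_published_genome.py MH745717.gb [other.gb ...]

Downloads are NOT performed here: fetch the focal record (GenBank accession
MH745717) and, optionally, the other Polyporales mitogenomes once, then
point this script at the local files. Each computed quantity is printed
next to the published value.
"""

import sys

from mitocomp.accession import replication_report

if len(sys.argv) < 2:
    sys.exit(__doc__)

report = replication_report(sys.argv[1], sys.argv[2:] or None)
print(f"{'quantity':<32} {'computed':>16} {'published':>16}")
for key, computed, published in report.rows():
    print(f"{key:<32} {str(computed):>16} {str(published):>16}")
print()
print("Computed values come entirely from this package's readers and")
print("statistics; multi-species rows need the comparison records too.")
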