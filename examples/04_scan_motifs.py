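"""Scan the packaged binding-site sequences for the GAS consensus.

Every shipped binding sequence is scanned on both strands against the
canonical TTCNNNGAA pattern; sequences missing the full 9-mer but
containing the TTC/GAA half-core are reported separately from sequences
containing neither.
"""

from stat5kit.annotation import concordance_report
from stat5kit.core_io import parse_site_tables

records = parse_site_tables()
counts, detail = concordance_report(records)

print(detail.to_string(index=False))
print()
print(f"consensus TTCNNNGAA (either strand): {counts['consensus']}/{len(records)}")
print(f"half-core TTC or GAA only:           {counts['core_only']}/{len(records)}")
print(f"neither:                             {counts['none']}/{len(records)}")
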