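"""Source counting and most-probable paths from probability tables.

Uses the bundled worked-example tables: one session with two clearly
separated sources, and one where a second source is visible only in
the last-activation (exit) statistics.
"""

import focimap as fm
from focimap.worked_examples import TWO_DISTANT_SOURCES, TWO_NEARBY_SOURCES, estimates_from_table

for name, table in (("two distant sources", TWO_DISTANT_SOURCES), ("two nearby sources", TWO_NEARBY_SOURCES)):
    first = estimates_from_table(table, "first")
    last = estimates_from_table(table, "last")
    n = fm.infer_source_count(first, last, alpha=0.1)
    paths = fm.extract_probable_paths(first, last, n)
    print(f"{name}: {n} source(s)")
    for p in paths:
        flags = " (reuses dominant entry)" if any(p.reused_slots) else ""
        print(f"  rank {p.source_rank}: path {p}  [FO-FI-LI-LO]{flags}")
    print()

print("each path reads: wave enters the outer loop at FO, reaches the inner")
print("loop at FI, and exits through LI (inner) and LO (outer)")
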