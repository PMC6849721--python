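"""Reading user ring data: long CSV and Tucson/RWL round trips.

Writes a small simulated population to the long CSV dialect, reads it
back, and parses a hand-written Tucson/RWL fragment (ring widths in
0.01 mm units, 999 stop marker), converting radial ring widths to
diameter increments.
"""

from pathlib import Path
import tempfile

import dendrobias as db

tmp = Path(tempfile.mkdtemp())

pop = db.simulate_population(
    db.RecruitmentSpec.unimodal(1950, 10, 5), db.GrowthParams(), 2000, seed=1, species="Demo"
)
csv_path = tmp / "rings.csv"
db.write_ring_table(pop, csv_path)
back = db.read_ring_table(csv_path)
print(f"CSV round trip: wrote {len(pop)} trees, read {len(back)} back")

rwl_path = tmp / "demo.rwl"
rwl_path.write_text(
    "SER01    1900   100   110   120   130   140   150   160   170   180   190\n"
    "SER01    1910   200   210   999\n"
)
series = db.read_rwl(rwl_path, species="Demo")[0]
print(
    f"RWL series {series.tree_id}: {series.recruitment_year}-{series.last_year}, "
    f"first ring {series.increments[0]:.2f} cm diameter increment "
    f"(1.00 mm radial ring width)"
)
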