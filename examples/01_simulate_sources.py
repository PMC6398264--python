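"""Generate the synthetic study substrate: two hospital databases + notes.

Creates an EHR-role database (patients, ICD-10-tagged encounters,
vital-sign rows), a physician-order-entry-role database (administrative
rows, vital-sign rows) and a corpus of templated Norwegian clinical
notes with known planted labels, all under one run directory.
"""

import json
import sqlite3

from carefuse.synthetic_data import SimConfig, write_run

config = SimConfig(seed=1, n_patients=10)
run = write_run(config, "scratch/example_run")

conn = sqlite3.connect(run / "dips.sqlite")
n_pat = conn.execute("SELECT COUNT(*) FROM patient").fetchone()[0]
n_enc = conn.execute("SELECT COUNT(*) FROM encounter").fetchone()[0]
n_meas = conn.execute("SELECT COUNT(*) FROM measurement").fetchone()[0]
manifest = json.loads((run / "manifest.json").read_text())

print(f"run directory: {run}")
print(f"EHR database: {n_pat} patients, {n_enc} encounters, {n_meas} measurement rows")
print(f"config hash: {manifest['config_sha256'][:16]}…")
# The same seed always reproduces byte-identical databases and corpus,
# so every downstream number in the other examples is reproducible.
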