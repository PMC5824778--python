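"""Install a store, generate a synthetic study, and import it.

Builds a four-sample, two-organism study (all four quantifier dialects),
loads metadata and per-sample analysis directories into the hybrid store,
and prints the per-stage double-entry report plus the integrity check.
"""

import tempfile

from transatlasdb import Store, fixtures, relational

with tempfile.TemporaryDirectory() as work:
    store = Store.install(f"{work}/store")
    fixtures.generate_study(fixtures.StudyConfig(seed=1), f"{work}/study")
    reports = fixtures.import_study(store, f"{work}/study")

    for name, report in reports.items():
        print(f"{name}:")
        for stage, (parsed, stored, status) in report.stages.items():
            # double-entry rule: every parsed row must also be stored
            print(f"  {stage:<11} parsed={parsed:<4} stored={stored:<4} {status}")

    violations = relational.check_referential_integrity(store.connection)
    print(f"referential integrity violations: {len(violations)}")
    print("(0 means every child row in the relational store has its parent)")
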