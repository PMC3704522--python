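"""Mitochondrial size and SR-contact statistics on the EM-style tables.

Computes, per simulated condition, the mean 2-D size (length x width) with
its SE and the SR contact frequency at the 30 nm criterion; compares the
pacing series by one-way ANOVA on size and pairwise Fisher's exact tests
on the per-mitochondrion contact tables, and the fission pair by t-test
and Fisher.

Writes results/morphometry/summary.csv and tests.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from mitocal import io, stats
from mitocal.morphometry import contact_sites, objects_from_table, size_stats

COHORT = Path("results/cohort")
OUT = Path("results/morphometry")
D_MAX_NM = 30.0

SERIES = {
    "pacing": ["efs_0hz", "efs_1hz", "efs_5hz"],
    "fission": ["vector_ctrl", "fission_blocked"],
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows, frames = [], []
    for path in sorted(COHORT.glob("em_*.csv")):
        name = path.stem.removeprefix("em_")
        objs = objects_from_table(io.read_object_table(path), d_max_nm=D_MAX_NM)
        mean, se, n = size_stats(objs)
        cs = contact_sites(objs, D_MAX_NM)
        rows.append({"group": name, "n": n, "mean_size2d_um2": mean,
                     "se_size2d": se, "contact_frequency": cs.frequency})
        frames.append(pd.DataFrame({"group": name,
                                    "size2d_um2": [o.size2d for o in objs],
                                    "contact": [o.contact for o in objs]}))
        print(f"{name:>16}: size {mean:.3f}±{se:.3f} µm²  "
              f"contacts {cs.n_contacts}/{cs.n_mito} ({cs.frequency:.0%})")
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "summary.csv", index=False, float_format="%.6g")

    per_obj = pd.concat(frames, ignore_index=True)
    tests = {}
    for series, groups in SERIES.items():
        sub = per_obj[per_obj.group.isin(groups)]
        _, size_tests = stats.summarize_groups(sub, "size2d_um2", "group")
        _, contact_tests = stats.summarize_groups(sub, "contact", "group")
        tests[series] = {"size": io._tests_to_json(size_tests),
                         "contact": io._tests_to_json(contact_tests)}
        print(f"{series}: size p = {size_tests[0].p:.3g} "
              f"({size_tests[0].test_name}); contact p = "
              + ", ".join(f"{t.p:.3g}" for t in contact_tests)
              + " (fisher_exact)")
    (OUT / "tests.json").write_text(json.dumps(tests, indent=1))
    print(f"\nwrote {OUT}/summary.csv and tests.json")


if __name__ == "__main__":
    sys.exit(main())
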