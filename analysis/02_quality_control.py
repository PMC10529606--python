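"""Filter the raw Fastloc streams: satellites, residual, speed.

Applies the three-stage quality control (fewer than five satellites;
residual above 30; 10 km/h forward speed sweep) and audits the removals
against the simulator's truth linkage.
"""

import json
from pathlib import Path

import numpy as np

from puptrack.qc import filter_fixes, read_fixes, write_fixes

OUT = Path("results/analysis")


def main() -> None:
    fixes = read_fixes(OUT / "fixes_raw.csv")
    links = json.loads((OUT / "links.json").read_text())

    kept, report = filter_fixes(fixes)
    write_fixes(kept, OUT / "fixes_qc.csv")
    (OUT / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    hit = n_out = 0
    for pid, lk in links.items():
        sub = fixes[fixes["id"] == pid].reset_index(drop=True)
        _, rep = filter_fixes(sub)
        removed = set(np.flatnonzero(rep.removal_reason.notna()))
        hit += len(set(lk["outlier_idx"]) & removed)
        n_out += len(lk["outlier_idx"])

    d = report.to_dict()
    frac = 100 * (d["n_input"] - d["n_kept"]) / d["n_input"]
    print(f"removed {d['n_input'] - d['n_kept']} of {d['n_input']} fixes "
          f"({frac:.1f}%): {d['n_removed_satellites']} satellites, "
          f"{d['n_removed_residual']} residual, {d['n_removed_speed']} speed")
    print(f"injected-outlier recall: {hit}/{n_out}")


if __name__ == "__main__":
    main()
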