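"""Quantify 12C and 13C formate in the GC-MS samples.

Fits the standards calibration (blank-subtracted analyte/ISTD area ratio vs
known concentration) and converts each experimental sample's m/z 136 and 137
channels to micromolar concentrations.  Outputs under results/formate/.
"""

import json
from pathlib import Path

from c1trace import GcmsSample, fit_calibration, quantify_formate, read_table

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "formate"


def as_sample(row):
    return GcmsSample(row.pa_136, row.pa_137, row.pa_138,
                      is_blank=bool(row.is_blank), sample_id=str(row.sample_id))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = read_table(SYN / "gcms_samples.csv")
    truth = json.loads((SYN / "ground_truth.json").read_text())

    blanks = df[df.is_blank]
    cal = fit_calibration(
        [(float(r.standard_um), as_sample(r))
         for r in df[df.is_standard].itertuples()],
        [as_sample(r) for r in blanks.itertuples()],
    )
    print(f"calibration: conc = {cal.slope:.3f} x ratio + {cal.intercept:.3f} "
          f"uM (r^2 = {cal.r_squared:.5f})")

    blank = GcmsSample(blanks.pa_136.mean(), blanks.pa_137.mean(),
                       blanks.pa_138.mean())
    rows = []
    for r in df[~df.is_blank & ~df.is_standard].itertuples():
        c12, c13 = quantify_formate(as_sample(r), blank, cal)
        rows.append({"sample_id": r.sample_id, "c12_formate_um": c12,
                     "c13_formate_um": c13})
        print(f"  {r.sample_id}: 12C {c12:.2f} uM, 13C {c13:.2f} uM")
    print(f"truth: 12C {truth['gcms']['c12_um']:.2f} uM, "
          f"13C {truth['gcms']['c13_um']:.2f} uM")
    (OUT / "formate_concentrations.json").write_text(
        json.dumps({"calibration": {"slope": cal.slope,
                                    "intercept": cal.intercept},
                    "samples": rows, "truth_um": truth["gcms"]},
                   indent=2) + "\n")


if __name__ == "__main__":
    main()
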