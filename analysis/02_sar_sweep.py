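#!/usr/bin/env python
"""SAR safety sweep of the layered capacitive-coupling circuit model.

Sweeps the insulation/scalp/skull/brain stack (5 um / 1 mm / 1 mm / 10 mm,
coupling area 0.78e-5 m^2) from 100 kHz to 5 MHz under the +/-2.5 V burst
drive (60 us pulses at 130 Hz), under both the duty-cycled and the
continuous-carrier RMS conventions, and reports the maximum brain-layer
specific absorption rate against the 2 W/kg localized-exposure limit.

Writes results/sar-sweep-reference.{json,csv}.
"""

from hydrostim.pipeline import run_scenario


def main() -> None:
    report = run_scenario("sar-sweep-reference", out_dir="results")
    for conv, sar in report["max_sar_w_per_kg"].items():
        print(f"max brain SAR ({conv} RMS): {sar:.3e} W/kg")
    verdict = "within" if report["within_limit"] else "EXCEEDS"
    print(
        f"overall max {report['max_sar_overall_w_per_kg']:.3e} W/kg -> "
        f"{verdict} the {report['sar_limit_w_per_kg']} W/kg limit"
    )
    print("wrote results/sar-sweep-reference.{json,csv}")


if __name__ == "__main__":
    main()
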