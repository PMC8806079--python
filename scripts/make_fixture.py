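"""Regenerate the bundled n=500 fixture cohort.

Run from the repository root:  python scripts/make_fixture.py
"""

from pathlib import Path

from thirdvar.synthetic import SyntheticParams, generate_cohort
from thirdvar.datamodel import write_cohort

FIXTURE_PARAMS = SyntheticParams(n=500, seed=20260904, ltl_output="both")


def main() -> None:
    dest = Path(__file__).resolve().parents[1] / "src" / "thirdvar" / "data" / "cohort_n500.csv"
    dest.parent.mkdir(parents=True, exist_ok=True)
    write_cohort(generate_cohort(FIXTURE_PARAMS), dest)
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
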