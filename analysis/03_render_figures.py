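"""Render the three diagnostic figures from the analysis results.

Position histogram with fitted densities, width-vs-position trade-off
with quantile curves and the null band, and the endangered residual
plots, written to results/figures/.
"""

from pathlib import Path

from npniche.figures import run_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results" / "analysis"
    out = ROOT / "results" / "figures"
    for path in run_report(results, out):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
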