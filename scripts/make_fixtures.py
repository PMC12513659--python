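"""Regenerate the packaged synthetic datasets under src/vergebayes/data/.

The registry in vergebayes.synthetic_data defines each fixture's generator
parameters; generation is fully seeded, so re-running this script reproduces
the shipped files byte for byte.
"""

from pathlib import Path

from vergebayes.synthetic_data import regenerate_fixtures

if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "vergebayes" / "data"
    for path in regenerate_fixtures(out):
        print(f"wrote {path}")
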