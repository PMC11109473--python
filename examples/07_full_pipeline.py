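"""The full configured pipeline, end to end, on a synthetic preset.

Equivalent to `isodiff run --config cfg.yaml`. Writes derived tables,
result tables, SVG/PNG figures, logs, and a manifest with the config
hash and seed; the same config + seed always reproduces identical tables.
"""

from isodiff.config import parse_config
from isodiff.pipeline import run_pipeline

cfg = parse_config(
    {
        "dataset": {"preset": "ldh_ko_48h"},
        "comparisons": [
            {"groups": [{"condition": "KO"}, {"condition": "control"}]}
        ],
        "statistics": {"seed": 42},
        "pca": {"enabled": True, "quantity": "total_abundance"},
        "output_dir": "example_pipeline_output",
    }
)
out = run_pipeline(cfg)
print("outputs written under", out)
for p in sorted(out.rglob("*")):
    if p.is_file():
        print(" ", p.relative_to(out))
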