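"""Write a synthetic benchmark to disk in standard text formats.

Produces a .rnk score list, a tab-delimited network edge list, a GMT
pathway collection and a truth-label table — the same formats the
command-line interface consumes — so the synthetic data can be used as a
smoke test for the full file-based pipeline:

    pathprop run --rnk out/scores.rnk --network out/network.edgelist \
        --gmt out/pathways.gmt --method netprop --seed 7 --out out/run
"""

import tempfile
from pathlib import Path

from pathprop import SynthConfig, generate, write_files

outdir = Path(tempfile.mkdtemp(prefix="pathprop_synth_"))
data = generate(SynthConfig(n_genes=300, n_pathways=25, seed=7))
paths = write_files(data, outdir)

print(f"planted signal pathways: {', '.join(data.truth)}")
for kind, path in paths.items():
    n_lines = sum(1 for _ in open(path))
    print(f"{kind:8s} {path}  ({n_lines} lines)")
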