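#!/usr/bin/env bash
# Full pipeline from the shell: simulate a locus, then fine-map it.
set -euo pipefail

locusfine simulate --m 100 --rho 0.9 --lam 10 --seed 11 --out demo_locus
locusfine finemap \
    --sumstats demo_locus/sumstats.tsv \
    --ld demo_locus/ld.tsv \
    --w 0.04 --level 0.95 --bins decay \
    --out demo_finemap
cat demo_finemap/run_metadata.yaml
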