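#!/usr/bin/env python
"""Colocalization of two association tracks over a locus window.

Simulates 500-kb-style locus tracks (200 shared SNPs) in three scenarios —
one shared causal SNP, two distinct causal SNPs, and no association — and
computes posterior probabilities PP0-PP4 under the default single-causal
priors (p1 = p2 = 1e-4, p12 = 1e-5).
"""

import sys
from pathlib import Path

import pandas as pd

from burdenmr import coloc, simcohort as sc
from burdenmr import io as bio

OUT = Path("results/coloc")
SEED = 23


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    scenarios = [
        ("shared_causal", dict(shared=True)),
        ("distinct_causal", dict(shared=False)),
        ("null_locus", dict(shared=True, effect1=0.0, effect2=0.0)),
    ]
    for name, kw in scenarios:
        t1, t2, info = sc.simulate_coloc_locus(200, seed=SEED, **kw)
        bio.write_table(t1, OUT / f"{name}_track1.tsv")
        bio.write_table(t2, OUT / f"{name}_track2.tsv")
        res = coloc.coloc_posteriors(t1, t2)
        rows.append({"scenario": name, **res.as_dict()})
        top = res.pp.argmax()
        print(f"{name}: " + ", ".join(f"{h} = {v:.3g}"
                                      for h, v in res.as_dict().items())
              + f"  -> H{top} favoured")
        if name == "shared_causal":
            lead = res.snp_pp_h4.idxmax()
            print(f"  lead shared-causal SNP {lead} "
                  f"(per-SNP posterior {res.snp_pp_h4.max():.3f})")
    bio.write_table(pd.DataFrame(rows), OUT / "coloc_posteriors.tsv")
    print(f"wrote {OUT}/coloc_posteriors.tsv")


if __name__ == "__main__":
    sys.exit(main())
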