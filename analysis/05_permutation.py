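"""Network-randomization significance test for the degree model.

The observed centrality coefficients are located within a null
distribution built by refitting the final model on rewired networks
(rewiring intensity drawn Uniform(0, 1) per run).  The lower-tail p asks
whether the observed coefficient is more negative than expected from
randomized networks.
"""

import sys

import pandas as pd

from lousenet import PermutationConfig, build_frame, permutation_test
from lousenet.dominance import dominance_from_records
from lousenet.io import load_agonistic, load_attributes, load_scans, \
    write_table
from lousenet.models import prune_interactions

R = int(sys.argv[1]) if len(sys.argv) > 1 else 500
SEED = int(sys.argv[2]) if len(sys.argv) > 2 else 11

scans = load_scans("results/data/scans.csv")
attributes = load_attributes("results/data/attributes.csv")
females = sorted(attributes["id"].unique())
cents = pd.read_csv("results/centrality.csv", comment="#")
lice = pd.read_csv("results/lice_load.csv", comment="#")
dom = dominance_from_records(load_agonistic("results/data/agonistic.csv"),
                             females)

frame = build_frame(lice, cents, dom.rank, attributes, "degree")
final, _ = prune_interactions(frame)
config = PermutationConfig(R=R, seed=SEED, tail="lower")

rows = []
for term in [n for n in final.names if "centrality" in n]:
    res = permutation_test(scans, females, frame, final, term, config)
    rows.append(res.to_dict())
    flag = "significant" if res.significant else "not significant"
    print(f"{term}: beta_obs={res.beta_obs:+.3f} "
          f"p(beta_obs < beta_rand)={res.p_empirical:.3f} ({flag} at the "
          f"95% criterion, R={R})")
write_table(pd.DataFrame(rows), "results/permutation_degree.csv")
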