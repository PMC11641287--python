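"""Predict miRNA seed sites on a circular transcript.

Builds a 300-nt circRNA with one 8mer site planted across the back-splice
junction, scans it both as a ring and as a linear sequence, and scores the
predicted sites.  Only the circular scan sees the junction-spanning site.
"""

import numpy as np

from circaxis import context_percentile, context_score, find_seed_sites
from circaxis.sponge import _revcomp

rng = np.random.default_rng(5)
mirna = "UAGCUUAUCAGACUGAUGUUGA"
site8 = _revcomp(mirna[1:8]) + "A"  # target site, 5'->3'

circ = list("".join(rng.choice(list("AUCG"), size=300)))
for i, c in enumerate(site8):        # plant the site across the junction
    circ[(296 + i) % 300] = c
circ = "".join(circ)

for circular in (True, False):
    sites = find_seed_sites(circ, mirna, circular=circular)
    print(f"circular={circular}: {len(sites)} site(s)")
    for s in sites:
        context_score(s, circ, circular=circular)
        print(f"  {s.site_type} at position {s.position}, score {s.score:.3f}")

sites = [context_score(s, circ) for s in find_seed_sites(circ, mirna)]
if sites:
    context_percentile(sites)
    print("percentiles (100 = strongest in this scan):",
          [round(s.percentile, 1) for s in sites])
# positions are 0-based on the linearized circle starting at the junction;
# the planted site sits at 296 and wraps around to position 3.
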