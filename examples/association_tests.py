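"""Test whether infection frequency differs between sexes or colour morphs.

With expected cell counts below five the chi-square approximation is
unreliable, so the exact test enumerates every table with the observed
margins.
"""

from mitosweep import fisher_exact, select_test

sex = [[72, 14], [1, 1]]          # infected/uninfected x female/male
morph = [[27, 22, 23], [0, 0, 1]]  # infected/uninfected x A/I/O female morphs

chosen = select_test(sex)
print(f"infection x sex: {chosen['test']} chosen, p = {chosen['p']:.2f}")
print(f"infection x morph: p = {fisher_exact(morph):.2f}")
print("neither p is small: infection is independent of sex and morph here")
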