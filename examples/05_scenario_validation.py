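"""Run the packaged literature-scenario library.

Each scenario sets inputs/mutations mimicking an experimental condition and
compares the trap-space phenotype readout against the reported behaviour.
Score codes: 1 = match, 0 = conflict, -1 = undefined.
"""

from raflsbool import (
    fixture_rafls,
    fixture_rafls_unmodified,
    run_scenario,
    scenario_library,
)

modified = fixture_rafls()
unmodified = fixture_rafls_unmodified()

print(f"{'scenario':42s} {'phenotype':28s} exp obt score")
for sc in scenario_library():
    net = modified if sc.variant == "modified" else unmodified
    res = run_scenario(net, sc)
    for ph, expected in sc.expected.items():
        flag = " (known conflict)" if sc.known_conflict else ""
        print(f"{sc.name:42s} {ph.split('_phenotype')[0]:28s} "
              f"{expected:3d} {res.obtained[ph]:3d} {res.scores[ph]:4d}{flag}")

print("\nReading: the two score-0 rows are the documented model conditions — "
      "TNF or IL-17 alone cannot activate inflammation without the "
      "IKBA/NFKB/RELA complex; their *_plus_NFKB counterparts score 1.")
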