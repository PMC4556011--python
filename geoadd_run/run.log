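2026-09-30 21:02:43,198 INFO created output directory /tmp/pytest-of-root/pytest-1/test_simulate_command0/out
2026-09-30 21:03:21,754 INFO created output directory /tmp/pytest-of-root/pytest-2/test_simulate_command0/out
2026-09-30 21:14:31,547 INFO created output directory /tmp/pytest-of-root/pytest-3/test_simulate_command0/out
2026-09-30 21:16:23,638 INFO created output directory /tmp/pytest-of-root/pytest-4/test_simulate_command0/out
2026-09-30 21:19:54,528 INFO created output directory /tmp/pytest-of-root/pytest-5/test_simulate_command0/out
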