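# Surface rule templates for connection extraction: one rule per line,
#   <rule_id> <TAB> <pattern>
# Pattern tokens are space-separated; alternatives use '|'; optional tokens
# are wrapped in [...]; {A} and {B} are brain-region slots.  Articles and
# the words "region(s)", "nucleus"-modifiers etc. (see FILLER in
# relations.py) may appear freely between pattern elements.  A slot followed
# by "and <region>" distributes over the conjuncts: "projection from A to C
# and D" yields the pairs (A,C) and (A,D).
r1	projection|projections from {A} to {B}
r2	{A} project|projects|projected [directly|densely|heavily|mainly|primarily] to {B}
r3	{B} receive|receives|received projection|projections|input|inputs|afferents from {A}
r4	{A} innervate|innervates|innervated {B}
r5	efferents|axons from {A} [terminate|terminates|terminating] in|to {B}
r6	afferents to {B} arise|arises|originate|originates from|in {A}
r7	{A} send|sends|sent axons|fibers|fibres|projections to {B}
r8	connection|connections between {A} and {B}
r9	{A} is|are reciprocally connected with|to {B}
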