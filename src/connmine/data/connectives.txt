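# Connective lexicon: one lowercased token per line.  A sentence containing
# any of these is treated as potentially asserting a connection between the
# brain regions it mentions.  Lines starting with '#' are comments.
project
projects
projected
projecting
projection
projections
innervate
innervates
innervated
innervating
innervation
afferent
afferents
efferent
efferents
input
inputs
terminate
terminates
terminated
terminating
originate
originates
originated
originating
arise
arises
arose
arising
send
sends
sent
sending
axons
fibers
fibres
connect
connects
connected
connection
connections
connectivity
invade
invades
invaded
invading
pathway
pathways
tract
tracts
linked
links
link
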