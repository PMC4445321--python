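taxon_id	label	variants
10114	Rattus	rat|rats|rattus|rattus norvegicus|sprague-dawley|wistar
10088	Mus	mouse|mice|mus|mus musculus|murine
9606	Homo Sapiens	human|humans|homo sapiens|man|patients|patient
314293	Simiiformes	monkey|monkeys|macaque|macaques|primate|primates|simiiformes|baboon|marmoset
7711	Chordata	chordata|ferret|ferrets|rabbit|rabbits|guinea pig|guinea pigs|pigeon|pigeons|turtle|turtles|zebrafish
9681	Felidae	cat|cats|feline|felidae|kitten|kittens
9615	Canis	dog|dogs|canine|canis|puppy|puppies
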