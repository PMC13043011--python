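# positive-valence emotion keywords (one per line)
happy
glad
good
great
wonderful
excellent
amazing
love
loved
loving
joy
joyful
excited
exciting
hopeful
hope
calm
relaxed
peaceful
content
grateful
thankful
proud
confident
energetic
refreshed
rested
motivated
cheerful
optimistic
pleasant
enjoy
enjoyed
fun
satisfied
strong
better
best
fine
well
positive
awesome
delighted
comfortable
encouraged
inspired
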