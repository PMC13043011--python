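# negative-valence emotion keywords (one per line)
sad
unhappy
bad
terrible
awful
horrible
hate
hated
angry
anger
mad
upset
worried
worry
anxious
anxiety
stressed
stress
tired
exhausted
fatigued
drained
weary
depressed
depressing
down
low
hopeless
lonely
alone
afraid
scared
fear
nervous
frustrated
frustrating
miserable
gloomy
worse
worst
pain
painful
hurt
overwhelmed
restless
irritable
guilty
ashamed
empty
numb
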