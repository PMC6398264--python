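# Norwegian stopword list (bokmål core), versioned in-repo so that
# analysis goldens stay stable.  One word per line.
og
i
jeg
det
at
en
et
den
til
er
som
på
de
med
han
av
ikke
der
så
var
meg
seg
men
ett
har
om
vi
min
mitt
ha
hadde
hun
nå
over
da
ved
fra
du
ut
sin
dem
oss
opp
man
kan
hans
hvor
eller
hva
skal
selv
sjøl
her
alle
vil
bli
ble
blitt
kunne
inn
når
være
kom
noen
noe
ville
dere
deres
kun
ja
etter
ned
skulle
denne
for
deg
si
sine
sitt
mot
å
meget
hvorfor
dette
disse
uten
hvordan
ingen
din
ditt
blir
samme
hvilken
hvilke
sånn
inni
mellom
vår
hver
hvem
hvis
både
bare
enn
fordi
før
mange
også
slik
vært
begge
siden
hos
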