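# pre2pub synthetic lexicon v1 (pseudo-words; deterministic)
bafais
baidrail
baidrun
baispaipru
banair
bapomit
batraid
beafux
beapazaish
beathish
beazix
bechedrul
bejoux
beteajish
bethispoun
bijiod
bikux
biobalit
bioclack
biojaspis
biokuchit
bioplick
bioraidreax
biosaid
bisat
bisouplem
bitealou
bogedreas
botut
boudril
bouloux
boumeax
bragolud
braimir
braitrun
brasus
brathofled
brator
breacheax
breaked
breameaclar
breapliosh
breazebaick
bredraix
bremom
brioflefloum
briolifiox
brioread
briothouck
briotriock
briplior
brithidrir
brobios
brocen
broflead
brohet
brougid
brougrain
broujoul
broulacat
brudrat
brulaick
bruplugru
brupouce
brustoushut
bruten
bruthiom
budam
cafax
caiplos
caiziruck
caizoufir
cajuck
capaclod
cariox
ceabeash
ceadil
ceapriosh
ceavair
cechoud
cefior
cepliol
cethear
ceveachouck
chadun
chaichaid
chaigeat
chaitrailu
chanaid
chaspion
cheatraim
chedroul
cheplet
chibrocheal
chidread
chikul
chiochoun
chiodeasout
chiorougriol
chiotroflem
choclaix
chohioban
chosta
chotur
chouvoux
chufeax
chugor
chutiteack
cigrat
claceprus
clagrear
claibailoud
claicleasho
clamain
clapleanoud
clashadis
claspeacluck
cleachispat
cleatrigrum
clidiod
cligoul
cliobuck
cliodex
cliodi
cliojion
cliolaibrain
clioristain
cliothoul
clishimiock
clitoum
cloniliol
clopiol
cloufegir
cloureat
cloutoush
clugrum
clusim
clutaid
cluthios
cluvofer
cobroul
coclur
cogrit
cogropou
cohefliosh
comuthais
copabir
coukaid
coulox
coumaspos
cuflotreal
cugraipail
cugut
dafluplock
daifod
daihiod
daitrur
dajivoux
daplul
deadrel
deci
dedus
diocloveam
diothiofim
diozulea
diplus
diprejaim
dobroufuck
dohaflail
domudrel
doseash
douchesh
doujeack
douriovel
drabrogio
draiclul
draidraim
draiflaish
drailos
draipair
draishiod
draithul
drapiod
draru
dreacun
dreageash
dreagoun
dreami
drekain
drekit
drelaigoul
dreleazit
dreplick
dreteam
drikisoun
driopreaplut
driostais
driosu
drobraidir
drotheri
droupir
droution
drusheatack
druspoud
dujut
dunead
dutechous
faifiom
faimotoux
faitud
faizous
feabio
feabudear
feaplai
feazock
febiom
fechen
fegeset
feraid
fethock
fetregix
figait
fiochi
fiotoun
fipeax
fishios
fispux
fivet
flachir
flaicechit
flaidripe
flailupram
flaitheathis
flalefuck
flaplash
fleafom
fleapros
fleastaifis
fleathas
flebrou
flebud
fleclid
flicail
flidroum
flioflour
fliohush
fliorabean
flioshios
fliotiot
flisar
flizol
floclouger
flogrepeack
flonal
flousais
flouthoux
flujaid
flustodick
focax
fochet
foleakous
folen
fopriox
foudrougel
foudruzo
foukiomoul
foushiopem
fouvagrem
fubes
fubiox
fubriomoush
fugrouplan
fuset
fushaick
fuvunai
gaflux
gaibraish
gaigrot
gaitre
gaizaick
gamux
gasteas
gateapril
gedrioclid
gedron
gedruck
gegiod
gepres
gilinex
giobion
giozex
gipleshio
goplusol
goprior
goseadrock
gouhea
gounean
gouviociock
graihush
granex
grasion
greahuck
greasteash
greatoucaix
gredrejio
grehethol
grejear
grenazuck
grenousut
gricux
gridean
griogram
griopavail
griopran
grocloplick
grocoum
grogolear
groled
groujir
grourad
grouspit
grouvu
gruchir
gruflux
gruhogead
gruplameat
gruste
gruzid
gubaru
gudreteam
gufoul
gumit
hadrinid
haija
haliolai
hamud
hateal
heajux
heakouck
heameadread
heler
hepleaflot
hepraix
hespeane
hibrais
hifloshit
higrun
higuchion
hihior
hiobax
hiochal
hishux
houdiopeas
hougear
houspeck
houtout
hoviock
hudrus
jaifli
jaiflux
jaikeax
janiotuck
japail
jazit
jeacum
jeafom
jeamailaick
jeamos
jeasack
jeates
jedreveal
jegaciock
jestod
jetrios
jidrilaick
jiogesh
jiomux
jiopaish
jioplashion
jioshos
jochaiclod
jochoul
jodit
jofoun
jogream
jospeadrour
joushoubios
jouzair
jubaiplail
juclaim
julai
junabut
kaimaish
kaispon
kaistai
kaplaid
katraiflais
keava
kethukai
kidis
kiobemaix
kiochechas
kiocios
kiocod
kiopredrait
kiotribrail
kisaijoul
koceash
kocod
koshox
koubid
koukea
kousaibiod
kouspoukil
kouzaistox
kozo
kuclait
kunat
kuplaid
kuspish
kuzio
laiflaish
laigrabrair
laithaiclead
leajoush
leater
leatread
legroud
lehosh
lepear
lepromem
ligrun
liodio
liomaish
litejion
lociospim
lolunos
lopes
loudrosh
loufoupriot
louhaish
loukougeck
louziot
luchou
ludeash
lugidras
macloum
magoun
maidar
maishipo
maisout
maizuriod
mako
maspaish
mavested
mearinid
mebricar
meded
megriod
metai
miflait
miofios
miozen
mocock
mohiofoul
monul
moudaish
moujilos
mozom
mucuck
mugroukox
mushaix
naigipliom
naimaix
naithoush
naitriocliox
naivopit
neabroflin
neapun
neasher
neclear
nibogio
nikaned
niocadair
niohadoush
nioprehiod
niotick
nohougread
noleaveash
nomit
nopiox
noprait
noudroclaish
nousock
nuplagream
nuspaifain
nutrick
pacaded
paduspas
padux
pagad
paibrusteat
paimaim
paisheahid
paitraid
paiziosh
papren
patod
peachea
peaclaish
peacliothait
peafosh
peataiplim
peatraim
pevaix
picliod
pidriod
pijosh
pinen
piosteal
piotrom
pipion
pithut
pitreax
plaibiot
plaibrastix
plaigios
plainair
plaiteam
plashaikous
pleajed
pleapain
pleatetet
pledios
plediox
pleliciom
pleplir
plepom
plepospai
plichaspout
pliobrougoud
pliociot
pliomud
plionus
plioplux
pliotrijesh
plipriocash
plobrous
plocluflix
plonim
plopreasteal
plospouthu
ploufosh
plougroush
ploumot
ploupred
pludrishiol
plufex
plumeax
pluspiox
pluvojax
poder
pomegrock
pomem
popeam
porai
pouran
pousel
pousir
prabiod
praidir
praimai
praipiox
praithud
preacliprid
preacou
preagesh
preastougrul
preavu
premit
prethou
prethouchim
prigrumim
prijaix
priobren
prodegror
progiojor
projix
proloum
proshapriox
protrai
protros
prouzat
prubriogroum
prudouck
prugrat
pruleclur
pruluck
pugick
pugream
pushun
rados
rafiozer
raichead
raifeck
raiziox
rasohuck
reafleal
reagrock
reasou
reatras
resain
riobrax
riocheshox
rioclaijiock
riomar
rione
rionick
rioprinot
riotrish
rodejick
roproum
roukairead
rucluveck
rupleabrou
rusaid
rusheas
saigekior
saigrot
saisibril
sakijil
seaclojar
seaflot
seakear
sealios
sebout
secluzel
sefiozol
seflosh
seliosto
sesios
shaipen
shakoul
shapraid
shasal
shasiogiod
sheaclen
sheahel
shealais
shealim
sheapleal
sheasoun
shibramaim
shibrish
shideas
shimeack
shioclis
shiolirul
shionad
shioplifloum
shiotron
shioviolock
shiozehos
shodochuck
shodrothe
shosedaix
shoshuvoun
shouchot
shoujod
shoupliocin
shouzaick
shudriflear
shuhair
shupeaheax
shupriosh
shuspin
sibeax
sigus
silotraid
siobeal
sioclut
siocouproun
siograck
siopram
sodim
soju
sokourais
sopreajeas
souchun
souduck
souhoux
soutiospin
sozojuck
spabron
spachaix
spaimuciosh
spamaigax
speachopul
spesush
spicioheat
spidai
spigit
spijus
spikai
spimit
spionoum
spiothai
spiozush
spipeagreash
spiplot
spiprick
spithiojed
spochothun
spoforat
spostax
spoteam
spotes
spothugeas
spoubeagail
spouchear
spoulibrain
spovex
spuchail
spudi
staicunaick
staidras
staidrick
staigishon
staigos
staishax
staisteck
staivour
stamustim
stapri
steatreat
steazedream
stekailea
stelos
stestouck
sticlel
stigral
stihoun
stioflalir
stioples
stiozeck
stispeack
stithegrex
stizimon
stoufeal
stoustex
stoustodid
stuchosh
stuchoux
stuflum
stulesaid
stushosh
stuthus
sulustesh
taclion
taikalea
takiom
taplosh
tateat
tathisis
teachush
teaclai
teatal
tenakar
tenit
tepron
teproux
tetraire
thacho
thaflon
thaidais
thaiflaistor
thaigahaick
thaipan
thaistiobeck
thathur
thazes
theajotreas
theaspum
thedati
thethetu
thijoudiosh
thimi
thiocoush
thiopoclick
thioprus
thiotreash
thipraisock
thitas
thiter
thouthous
thouvout
thucufin
thupeaken
thusock
tiboul
tiofush
tiogriolear
tiokoud
tioroclun
tioshaguck
tiplex
tistoun
titrot
titrutrim
tocos
tofad
tosud
touchour
toufioclud
traciom
tradravul
traibeax
traijaispout
traizail
trasiom
treavous
trekea
tremioshiom
trespunes
trimuroud
triogid
triojot
triovashoum
trogishaim
trojegros
trosait
trosous
trothix
trothuplaish
trouzaix
trupoum
trustea
tudior
tusefex
tutane
tutheal
vadailir
vaiflosh
vaisefles
vathaidroush
veagrutiot
veamubroul
veasous
vecea
vechuzock
vedris
vegrash
velom
venaix
vepleafu
verot
viobu
viodis
viosaichash
vioshin
voriol
vouclait
vouclod
voushem
voutes
vubrai
vuchear
vuriotout
zapir
zashoux
zasou
zatripeat
zeabiochesh
zeachesh
zeaflour
zeaprox
zeaspud
zelougin
zestous
zibre
zihiock
ziolit
zioprabrack
zioprud
ziorair
ziozazail
ziprut
zispouplum
zogroum
zonairud
zoplairun
zorihior
zospout
zoucuchid
zoufeash
zoulen
zousut
zuclis
zukiot
zupin
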